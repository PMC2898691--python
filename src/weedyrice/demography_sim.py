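"""Coalescent simulation of the weedy-rice founder model.

The demographic model is a two-population founder scenario: a weed founder
lineage of effective size eta_p (constrained equal to the progenitor's
eta_c) splits from its crop/wild progenitor at time tau_s; at tau_f
founder lineages arrive in the U.S. and pass through a bottleneck of size
eta_b; at tau_g the population recovers instantaneously to its current
size eta_r. Weeds are treated as fully selfing, which halves the effective
size of every weed-lineage epoch.

Simulation follows Hudson's coalescent conventions: time is measured in
units of 4*N_ref generations, population sizes as ratios to a reference
size N_ref derived from a reference per-site diversity, and each locus is
simulated on the continuous interval [0, 1) under the ancestral
recombination graph with infinite-sites mutation at per-locus rate
theta = 4*N_ref*mu*L and recombination rate rho (rho = theta by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemographicModel",
    "ScalingConfig",
    "CoalescentConfig",
    "ScaledDemography",
    "SimulatedLocus",
    "SimulatedDataset",
    "derive_reference_size",
    "to_coalescent_units",
    "constant_size_demography",
    "simulate_locus",
    "simulate_dataset",
    "rescale_estimate",
]


class ModelError(ValueError):
    """Raised when demographic parameters violate ordering or positivity."""


@dataclass(frozen=True)
class DemographicModel:
    """Founder-bottleneck model parameters in natural units.

    Sizes are effective numbers of (diploid) individuals; times are years
    before present. ``eta_p`` (the founder-lineage size between tau_s and
    tau_f) is constrained equal to ``eta_c``.
    """

    eta_c: float          # progenitor size, constant for the whole simulation
    eta_b: float          # bottleneck size between tau_f and tau_g
    eta_r: float          # current weed size, from tau_g to the present
    tau_s: float          # split from the progenitor (ybp)
    tau_f: float          # founding in the U.S. (ybp)
    tau_g: float          # instantaneous recovery/expansion (ybp)
    weed_selfing: bool = True

    def __post_init__(self) -> None:
        if not (self.tau_s >= self.tau_f >= self.tau_g >= 0):
            raise ModelError(
                f"time ordering violated: tau_s={self.tau_s} >= "
                f"tau_f={self.tau_f} >= tau_g={self.tau_g} >= 0 required"
            )
        for name in ("eta_c", "eta_b", "eta_r"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be >= 1 individual")

    @property
    def eta_p(self) -> float:
        return self.eta_c

    @property
    def bottleneck_intensity(self) -> float:
        """Percent decline in size during the bottleneck, 100*(1 - eta_b/eta_r)."""
        return 100.0 * (1.0 - self.eta_b / self.eta_r)


@dataclass(frozen=True)
class ScalingConfig:
    """Constants linking coalescent units to years and individuals."""

    n_ref: float                       # reference effective size (individuals)
    mu: float = 1e-8                   # per-nucleotide per-generation rate
    generation_time: float = 1.0       # years
    rho_over_theta: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_time <= 0 or self.n_ref <= 0:
            raise ModelError("mu, generation_time and n_ref must be positive")
        if self.rho_over_theta < 0:
            raise ModelError("rho_over_theta must be >= 0")

    @property
    def four_n_ref(self) -> float:
        return 4.0 * self.n_ref

    def theta_locus(self, length_bp: float) -> float:
        """Per-locus population mutation rate theta = 4*N_ref*mu*L."""
        return self.four_n_ref * self.mu * length_bp


def derive_reference_size(theta_per_kb: float, mu: float = 1e-8) -> tuple[float, float]:
    """Reference effective size from a per-kb diversity estimate.

    N_ref = (theta per site) / (4 mu); returns (N_ref, 4*N_ref). The default
    reference is the silent-site Watterson's theta of the wild progenitor,
    whose frequency spectrum is compatible with a constant-size population.
    """
    if theta_per_kb <= 0:
        raise ModelError("reference theta must be positive")
    n_ref = (theta_per_kb / 1000.0) / (4.0 * mu)
    return n_ref, 4.0 * n_ref


@dataclass(frozen=True)
class CoalescentConfig:
    """Sampling configuration: haploid sample sizes and the locus panel."""

    n_weed: int
    n_progenitor: int
    loci: tuple[tuple[str, int], ...]
    site_class_proportions: dict | None = None
    pop_labels: tuple[str, str] = ("weed", "progenitor")

    def __post_init__(self) -> None:
        if self.n_weed < 2 or self.n_progenitor < 2:
            raise ModelError("need at least 2 haplotypes per population")
        if any(length <= 0 for _, length in self.loci):
            raise ModelError("locus lengths must be positive")

    @classmethod
    def uniform_panel(cls, n_weed: int, n_progenitor: int, n_loci: int,
                      length_bp: int, **kw) -> "CoalescentConfig":
        loci = tuple((f"STS{i:03d}", length_bp) for i in range(n_loci))
        return cls(n_weed, n_progenitor, loci, **kw)


@dataclass(frozen=True)
class ScaledDemography:
    """Demography in Hudson units: sizes relative to N_ref, times in units
    of 4*N_ref generations, events ordered present -> past.

    Events are (time, kind, pop, value): kind 'size' resets a population's
    relative size, kind 'merge' moves all of a population's lineages into
    population ``value`` (a split, viewed backward in time).
    """

    initial_sizes: tuple[float, ...]
    events: tuple[tuple[float, str, int, float], ...] = ()

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ModelError("events must be ordered from present to past")
        if any(x <= 0 for x in self.initial_sizes):
            raise ModelError("population sizes must be positive")


def constant_size_demography(relative_size: float = 1.0) -> ScaledDemography:
    """Single constant-size population; the calibration baseline."""
    return ScaledDemography(initial_sizes=(relative_size,))


def to_coalescent_units(model: DemographicModel,
                        scaling: ScalingConfig) -> ScaledDemography:
    """Scale the founder model into Hudson units.

    Population 0 is the weed lineage, population 1 the progenitor. Full
    selfing multiplies every weed-lineage size by 0.5 (the progenitor is
    left unscaled). Backward in time the weed runs at eta_r until tau_g,
    eta_b until tau_f, eta_p until tau_s, then merges into the progenitor.
    """
    s = 0.5 if model.weed_selfing else 1.0
    n_ref = scaling.n_ref

    def t_scaled(years: float) -> float:
        return (years / scaling.generation_time) / scaling.four_n_ref

    events = (
        (t_scaled(model.tau_g), "size", 0, model.eta_b * s / n_ref),
        (t_scaled(model.tau_f), "size", 0, model.eta_p * s / n_ref),
        (t_scaled(model.tau_s), "merge", 0, 1),
    )
    return ScaledDemography(
        initial_sizes=(model.eta_r * s / n_ref, model.eta_c / n_ref),
        events=events,
    )


# ---------------------------------------------------------------------------
# The Hudson-style ARG simulator
#
# A lineage is [pop, birth_time, segments] where segments is a sorted list of
# (left, right, mask) tuples on [0, 1); mask is a bitmask of the sampled
# haplotypes the segment is ancestral to. Segments whose mask covers every
# sample have reached their MRCA and are dropped. Mutation opportunity is
# recorded per finished lineage as (mass, segments) with
# mass = duration * total ancestral length, and mutations are laid down
# afterwards at rate theta per unit (time x length).


def _merge_segments(a, b, full_mask):
    """Overlay two disjoint sorted segment lists, OR-ing masks and dropping
    fully coalesced material."""
    points = sorted({p for l, r, _ in a for p in (l, r)}
                    | {p for l, r, _ in b for p in (l, r)})
    out = []
    ia = ib = 0
    for lo, hi in zip(points, points[1:]):
        mask = 0
        for segs in (a, b):
            for l, r, m in segs:
                if l <= lo and r >= hi:
                    mask |= m
                    break
        if mask and mask != full_mask:
            if out and out[-1][1] == lo and out[-1][2] == mask:
                out[-1] = (out[-1][0], hi, mask)
            else:
                out.append((lo, hi, mask))
    return out


def _split_segments(segments, breakpoint):
    left, right = [], []
    for l, r, m in segments:
        if r <= breakpoint:
            left.append((l, r, m))
        elif l >= breakpoint:
            right.append((l, r, m))
        else:
            left.append((l, breakpoint, m))
            right.append((breakpoint, r, m))
    return left, right


class _UniformBuffer:
    """Buffered uniform(0,1) draws; one bulk numpy call per refill."""

    __slots__ = ("rng", "buf", "pos")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf = rng.random(256)
        self.pos = 0

    def next(self) -> float:
        if self.pos >= len(self.buf):
            self.buf = self.rng.random(256)
            self.pos = 0
        u = self.buf[self.pos]
        self.pos += 1
        return u


def simulate_locus(scaled: ScaledDemography, sample_sizes, theta: float,
                   rho: float, seed) -> "SimulatedLocus":
    """Simulate one locus under the scaled demography.

    ``sample_sizes`` gives the haploid sample size per population (ordered
    as in the demography). Returns segregating-site positions on [0, 1) and
    the 0/1 haplotype matrix (sites x samples, ancestral = 0).
    """
    if not (math.isfinite(theta) and math.isfinite(rho)) or theta < 0 or rho < 0:
        raise ModelError("theta and rho must be finite and non-negative")
    rng = np.random.default_rng(seed)
    uni = _UniformBuffer(rng)
    n_total = int(sum(sample_sizes))
    full_mask = (1 << n_total) - 1

    sizes = list(scaled.initial_sizes)
    if len(sample_sizes) != len(sizes):
        raise ModelError("sample_sizes must match the number of populations")

    lineages = []
    sample = 0
    for pop, n in enumerate(sample_sizes):
        for _ in range(int(n)):
            lineages.append([pop, 0.0, [(0.0, 1.0, 1 << sample)]])
            sample += 1

    records: list[tuple[float, list]] = []
    t = 0.0
    next_event = 0

    def close(lin, now):
        duration = now - lin[1]
        if duration > 0.0 and lin[2]:
            mass = duration * sum(r - l for l, r, _ in lin[2])
            if mass > 0.0:
                records.append((mass, lin[2]))

    while len(lineages) > 1:
        counts = [0] * len(sizes)
        for lin in lineages:
            counts[lin[0]] += 1
        coal_rates = [k * (k - 1) / x for k, x in zip(counts, sizes)]
        spans = [lin[2][-1][1] - lin[2][0][0] for lin in lineages]
        rec_rate = rho * sum(spans)
        total_rate = sum(coal_rates) + rec_rate

        if next_event < len(scaled.events):
            t_event = scaled.events[next_event][0]
        else:
            t_event = math.inf
        wait = (-math.log(1.0 - uni.next()) / total_rate
                if total_rate > 0 else math.inf)
        if t + wait >= t_event:
            t = t_event
            _, kind, pop, value = scaled.events[next_event]
            next_event += 1
            if kind == "size":
                sizes[pop] = float(value)
            elif kind == "merge":
                for lin in lineages:
                    if lin[0] == pop:
                        lin[0] = int(value)
            else:  # pragma: no cover
                raise ModelError(f"unknown event kind {kind!r}")
            continue
        if not math.isfinite(wait):  # isolated lineages with no future event
            raise ModelError("coalescent cannot complete: zero total rate")
        t += wait

        u = uni.next() * total_rate
        if u < rec_rate:
            # recombination: lineage chosen by span, breakpoint uniform in span
            target = u / rho
            acc = 0.0
            for i, s in enumerate(spans):
                acc += s
                if target < acc or i == len(spans) - 1:
                    break
            lin = lineages.pop(i)
            lo, hi = lin[2][0][0], lin[2][-1][1]
            bp = lo + uni.next() * (hi - lo)
            close(lin, t)
            left, right = _split_segments(lin[2], bp)
            for part in (left, right):
                if part:
                    lineages.append([lin[0], t, part])
        else:
            u -= rec_rate
            pop = len(coal_rates) - 1
            for p, rate in enumerate(coal_rates):
                if u < rate:
                    pop = p
                    break
                u -= rate
            members = [i for i, lin in enumerate(lineages) if lin[0] == pop]
            if len(members) < 2:  # float rounding in the rate scan
                pop = max(range(len(coal_rates)), key=lambda p: coal_rates[p])
                members = [i for i, lin in enumerate(lineages)
                           if lin[0] == pop]
            k = len(members)
            i = int(uni.next() * k)
            j = int(uni.next() * (k - 1))
            if j >= i:
                j += 1
            a = lineages[members[i]]
            b = lineages[members[j]]
            close(a, t)
            close(b, t)
            merged = _merge_segments(a[2], b[2], full_mask)
            for k in sorted((members[i], members[j]), reverse=True):
                lineages.pop(k)
            if merged:
                lineages.append([pop, t, merged])

    if lineages:  # single residual lineage: all its material is at MRCA
        lineages[0][2] = [s for s in lineages[0][2] if s[2] != full_mask]
        if lineages[0][2]:
            raise ModelError("unreachable: uncoalesced material remains")

    # infinite-sites mutations over the recorded branch material
    masses = np.array([m for m, _ in records])
    total_mass = float(masses.sum()) if len(masses) else 0.0
    n_mut = int(rng.poisson(theta * total_mass)) if total_mass > 0 else 0
    positions = np.empty(n_mut)
    masks = []
    if n_mut:
        cum = np.cumsum(masses)
        picks = rng.random(n_mut) * total_mass
        for m_i, pick in enumerate(picks):
            rec_idx = int(np.searchsorted(cum, pick, side="right"))
            rec_idx = min(rec_idx, len(records) - 1)
            segs = records[rec_idx][1]
            lens = [r - l for l, r, _ in segs]
            offset = rng.random() * sum(lens)
            for (l, r, mask), w in zip(segs, lens):
                if offset < w:
                    positions[m_i] = l + offset
                    masks.append(mask)
                    break
                offset -= w
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    if n_mut and n_total <= 63:
        mask_arr = np.array([masks[mi] for mi in order], dtype=np.uint64)
        shifts = np.arange(n_total, dtype=np.uint64)
        genotypes = ((mask_arr[:, None] >> shifts[None, :]) & 1).astype(np.int8)
    elif n_mut:     # arbitrary-width masks for very large samples
        genotypes = np.zeros((n_mut, n_total), dtype=np.int8)
        for row, mi in enumerate(order):
            mask = masks[mi]
            for s in range(n_total):
                if (mask >> s) & 1:
                    genotypes[row, s] = 1
    else:
        genotypes = np.zeros((0, n_total), dtype=np.int8)
    return SimulatedLocus("", positions, genotypes, 0)


@dataclass
class SimulatedLocus:
    locus_id: str
    positions: np.ndarray       # segregating-site positions on [0, 1)
    genotypes: np.ndarray       # int8, sites x haplotypes (0 ancestral)
    length_bp: int


@dataclass
class SimulatedDataset:
    """Independent simulated loci plus the configuration that produced them."""

    loci: list[SimulatedLocus]
    config: CoalescentConfig
    seed: int

    @property
    def total_length_bp(self) -> int:
        return sum(l.length_bp for l in self.loci)

    def locus_arrays(self) -> list[np.ndarray]:
        return [l.genotypes for l in self.loci]

    def to_snp_matrix(self):
        """Render to an :class:`~weedyrice.sts_io.SNPMatrix`, mapping
        continuous positions to integer columns (collisions re-drawn) and
        assigning site classes by the configured proportions."""
        import pandas as pd
        from .sts_io import SITE_CLASSES, SNPMatrix

        props = self.config.site_class_proportions
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(0xC1A55,)))
        site_rows, blocks, loci_rows = [], [], []
        for locus in self.loci:
            cols = _positions_to_columns(locus.positions, locus.length_bp, rng)
            order = np.argsort(cols)
            if props:
                names = list(props)
                probs = np.array([props[c] for c in names], dtype=float)
                probs /= probs.sum()
                classes = rng.choice(names, size=len(cols), p=probs)
                class_cols = _allocate_class_columns(
                    locus.length_bp, names, probs, cols[order],
                    classes[order])
            else:
                classes = np.array(["unclassified"] * len(cols))
                class_cols = {"unclassified": locus.length_bp}
            for k in order:
                site_rows.append({
                    "locus_id": locus.locus_id, "column": int(cols[k]),
                    "site_class": str(classes[k]), "major": "0", "minor": "1",
                })
                blocks.append(locus.genotypes[k])
            loci_rows.append({
                "locus_id": locus.locus_id, "length_bp": locus.length_bp,
                "n_all": locus.length_bp,
                **{f"n_{c}": int(class_cols.get(c, 0)) for c in SITE_CLASSES},
            })
        n_w, n_p = self.config.n_weed, self.config.n_progenitor
        lw, lp = self.config.pop_labels
        samples = pd.DataFrame({
            "sample_id": [f"{lw}_{i:03d}" for i in range(n_w)]
            + [f"{lp}_{i:03d}" for i in range(n_p)],
            "population": [lw] * n_w + [lp] * n_p,
        })
        genotypes = (np.array(blocks, dtype=np.int8) if blocks
                     else np.empty((0, n_w + n_p), dtype=np.int8))
        sites = pd.DataFrame(
            site_rows,
            columns=["locus_id", "column", "site_class", "major", "minor"])
        loci = pd.DataFrame(loci_rows).set_index("locus_id")
        return SNPMatrix(genotypes, sites, samples, loci)

    def to_alignments(self):
        """Render loci as STSAlignment objects (derived alleles as base
        substitutions on a random but reproducible reference)."""
        from .sts_io import STSAlignment

        matrix = self.to_snp_matrix()
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(0xA116,)))
        bases = np.array(list("ACGT"))
        sample_ids = matrix.samples["sample_id"].tolist()
        out = []
        for locus in self.loci:
            ref = rng.choice(bases, size=locus.length_bp)
            seqs = np.tile(ref, (len(sample_ids), 1))
            sel = matrix.sites["locus_id"] == locus.locus_id
            for _, site in matrix.sites[sel].iterrows():
                col = int(site["column"])
                alt_choices = [b for b in "ACGT" if b != ref[col]]
                alt = alt_choices[int(rng.integers(len(alt_choices)))]
                row_idx = matrix.sites.index[
                    (matrix.sites["locus_id"] == locus.locus_id)
                    & (matrix.sites["column"] == col)][0]
                carriers = matrix.genotypes[row_idx] == 1
                seqs[carriers, col] = alt
            out.append(STSAlignment(
                locus.locus_id, list(sample_ids),
                ["".join(row) for row in seqs]))
        return out

    def to_ms_text(self) -> str:
        """MS-style segregating-sites block, for cross-checking against
        external coalescent simulators."""
        lines = []
        for locus in self.loci:
            lines.append(f"// {locus.locus_id}")
            lines.append(f"segsites: {len(locus.positions)}")
            if len(locus.positions):
                lines.append("positions: "
                             + " ".join(f"{p:.5f}" for p in locus.positions))
                for hap in locus.genotypes.T:
                    lines.append("".join(map(str, hap)))
            lines.append("")
        return "\n".join(lines)


def _positions_to_columns(positions: np.ndarray, length_bp: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Map continuous positions to distinct integer columns; collisions are
    re-drawn uniformly among free columns."""
    if len(positions) > length_bp:
        raise ModelError(
            f"{len(positions)} segregating sites exceed locus length {length_bp}")
    cols = np.floor(positions * length_bp).astype(int)
    used: set[int] = set()
    out = np.empty(len(cols), dtype=int)
    for i, c in enumerate(cols):
        if c in used:
            free = [x for x in range(length_bp) if x not in used]
            c = int(free[int(rng.integers(len(free)))])
        used.add(int(c))
        out[i] = c
    return out


def _allocate_class_columns(length_bp, names, probs, snp_cols, snp_classes):
    """Split a locus's columns among site classes consistently with the
    classes already assigned to SNP columns (largest-remainder allocation
    of the remaining monomorphic columns)."""
    counts = dict.fromkeys(names, 0)
    for c in snp_classes:
        counts[str(c)] += 1
    remaining = length_bp - len(snp_cols)
    raw = probs * remaining
    base = np.floor(raw).astype(int)
    rem = raw - base
    for extra in np.argsort(-rem)[: remaining - int(base.sum())]:
        base[extra] += 1
    for name, extra in zip(names, base):
        counts[name] += int(extra)
    return counts


def locus_seed(master_seed: int, locus_index: int) -> np.random.SeedSequence:
    """Deterministic per-locus stream, invariant to the number of loci."""
    return np.random.SeedSequence(master_seed, spawn_key=(locus_index,))


def simulate_dataset(model: DemographicModel, scaling: ScalingConfig,
                     config: CoalescentConfig, seed: int) -> SimulatedDataset:
    """Simulate the full multi-locus panel: independent loci, per-locus
    theta = 4*N_ref*mu*L and rho = rho_over_theta * theta."""
    scaled = to_coalescent_units(model, scaling)
    sample_sizes = (config.n_weed, config.n_progenitor)
    loci = []
    for i, (locus_id, length) in enumerate(config.loci):
        theta = scaling.theta_locus(length)
        rho = scaling.rho_over_theta * theta
        locus = simulate_locus(scaled, sample_sizes, theta, rho,
                               locus_seed(seed, i))
        locus.locus_id = locus_id
        locus.length_bp = length
        loci.append(locus)
    return SimulatedDataset(loci, config, seed)


def rescale_estimate(scaled_value: float, locus_mutation_rate: float,
                     scaling: ScalingConfig, kind: str) -> float:
    """Convert mutation-scaled estimates to natural units.

    kind 'size': N = theta_hat / (4 u); kind 'time':
    years = (t_hat / u) * generation_time, with u the per-locus
    per-generation mutation rate (mu x locus length).
    """
    if locus_mutation_rate <= 0:
        raise ModelError("locus mutation rate must be positive")
    if kind == "size":
        return scaled_value / (4.0 * locus_mutation_rate)
    if kind == "time":
        return scaled_value / locus_mutation_rate * scaling.generation_time
    raise ValueError(f"unknown rescaling kind {kind!r}")
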