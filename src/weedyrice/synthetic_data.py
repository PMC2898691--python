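"""Generators for pseudo-observed panels with known truth.

Every stage of the pipeline is testable without sequence downloads: this
module produces multi-locus panels simulated under named founder-model
presets (with the generating parameters stored next to the data), small
hand-checkable alignments with planted site partitions, and cytoplasm
marker panels drawn from given cytotype frequencies.

The presets are illustrative parameter sets encoding the qualitative
findings for the two main U.S. weed groups — they are not estimates:

* ``SH`` (straw hull, indica-derived): divergence at the time of U.S.
  founding and a severe (99% decline) bottleneck;
* ``BHA1`` (black hull awned, aus-derived): an older, post-domestication
  divergence and a milder bottleneck.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .demography_sim import (
    CoalescentConfig,
    DemographicModel,
    ScalingConfig,
    SimulatedDataset,
    derive_reference_size,
    simulate_dataset,
)
from .sts_io import PopulationPanel, STSAlignment

__all__ = [
    "TruthRecord",
    "PRESETS",
    "default_scaling",
    "preset_model",
    "preset_config",
    "make_pseudo_observed",
    "make_toy_alignment",
    "make_cytotype_panel",
]

#: Reference silent-site Watterson's theta per kb for the wild progenitor
#: (O. rufipogon), the anchor for the reference size N_ref.
RUFIPOGON_SILENT_THETA_PER_KB = 7.787


def default_scaling(mu: float = 1e-8, generation_time: float = 1.0,
                    rho_over_theta: float = 1.0) -> ScalingConfig:
    n_ref, _ = derive_reference_size(RUFIPOGON_SILENT_THETA_PER_KB, mu)
    return ScalingConfig(n_ref=n_ref, mu=mu, generation_time=generation_time,
                         rho_over_theta=rho_over_theta)


# Preset parameters as ratios, resolved against N_ref at build time.
# eta_c ratios follow the observed crop/wild silent-diversity ratios
# (indica ~0.28, aus ~0.18 of the O. rufipogon reference).
PRESETS: dict[str, dict] = {
    "SH": dict(
        eta_c_ratio=0.28, eta_r_over_eta_c=0.06, eta_b_over_eta_r=0.01,
        tau_s=200.0, tau_f=200.0, tau_g=100.0,
        n_weed=24, n_progenitor=22,
        description="straw-hull weed vs indica: founding-time divergence, "
                    "99% bottleneck decline",
    ),
    "BHA1": dict(
        eta_c_ratio=0.18, eta_r_over_eta_c=0.2, eta_b_over_eta_r=0.3,
        tau_s=10_000.0, tau_f=200.0, tau_g=100.0,
        n_weed=15, n_progenitor=7,
        description="black-hull-awned weed vs aus: post-domestication "
                    "divergence, milder bottleneck",
    ),
}


@dataclass
class TruthRecord:
    """Generating parameters and seed stored alongside a pseudo-observed
    dataset, plus the qualitative signature the data should show."""

    preset: str | None
    model: dict
    scaling: dict
    n_weed: int
    n_progenitor: int
    n_loci: int
    locus_length_bp: int
    seed: int
    expected_signatures: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def preset_model(name: str, scaling: ScalingConfig) -> DemographicModel:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {list(PRESETS)}")
    p = PRESETS[name]
    eta_c = p["eta_c_ratio"] * scaling.n_ref
    eta_r = max(p["eta_r_over_eta_c"] * eta_c, 1.0)
    eta_b = max(p["eta_b_over_eta_r"] * eta_r, 1.0)
    return DemographicModel(eta_c=eta_c, eta_b=eta_b, eta_r=eta_r,
                            tau_s=p["tau_s"], tau_f=p["tau_f"],
                            tau_g=p["tau_g"])


def preset_config(name: str, n_loci: int = 48, length_bp: int = 500,
                  **kw) -> CoalescentConfig:
    p = PRESETS[name]
    return CoalescentConfig.uniform_panel(
        p["n_weed"], p["n_progenitor"], n_loci, length_bp, **kw)


def make_pseudo_observed(
    model: DemographicModel,
    scaling: ScalingConfig,
    config: CoalescentConfig,
    seed: int,
    preset: str | None = None,
    out_dir: str | Path | None = None,
) -> tuple[SimulatedDataset, TruthRecord]:
    """Simulate a pseudo-observed panel and its truth record; optionally
    write FASTA + population-map TSV + truth JSON to ``out_dir``."""
    dataset = simulate_dataset(model, scaling, config, seed)
    truth = TruthRecord(
        preset=preset,
        model=dict(eta_c=model.eta_c, eta_b=model.eta_b, eta_r=model.eta_r,
                   tau_s=model.tau_s, tau_f=model.tau_f, tau_g=model.tau_g,
                   weed_selfing=model.weed_selfing),
        scaling=dict(n_ref=scaling.n_ref, mu=scaling.mu,
                     generation_time=scaling.generation_time,
                     rho_over_theta=scaling.rho_over_theta),
        n_weed=config.n_weed, n_progenitor=config.n_progenitor,
        n_loci=len(config.loci),
        locus_length_bp=config.loci[0][1] if config.loci else 0,
        seed=seed,
        expected_signatures=dict(
            weed_diversity_below_progenitor=model.eta_b < model.eta_c,
            bottleneck_intensity_percent=model.bottleneck_intensity,
        ),
    )
    if out_dir is not None:
        write_dataset(dataset, truth, out_dir)
    return dataset, truth


def write_dataset(dataset: SimulatedDataset, truth: TruthRecord | None,
                  out_dir: str | Path) -> None:
    """Write the dataset in the same formats the readers consume: one FASTA
    per locus, a population map TSV, and the truth record JSON."""
    from .sts_io import write_population_map, write_sts_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alignments = dataset.to_alignments()
    for aln in alignments:
        write_sts_fasta(aln, out / f"{aln.locus_id}.fasta")
    lw, lp = dataset.config.pop_labels
    mapping = {sid: (lw if i < dataset.config.n_weed else lp)
               for i, sid in enumerate(alignments[0].sample_ids)}
    write_population_map(PopulationPanel(mapping), out / "populations.tsv")
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())


def make_toy_alignment(shared: int, private1: int, private2: int, fixed: int,
                       n1: int = 4, n2: int = 4, L: int = 40,
                       locus_id: str = "toy") -> tuple[STSAlignment,
                                                       PopulationPanel]:
    """Construct an alignment whose two-population site partition equals
    the planted counts exactly.

    Planted sites occupy the first columns; every polymorphism is carried
    by two haplotypes per polymorphic population, so no planted site is a
    pooled singleton.
    """
    n_sites = shared + private1 + private2 + fixed
    if n_sites > L:
        raise ValueError(f"cannot plant {n_sites} sites in {L} columns")
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haplotypes per population to plant "
                         "non-singleton polymorphisms")
    seqs = np.full((n1 + n2, L), "A", dtype="U1")
    col = 0
    for _ in range(shared):
        seqs[0:2, col] = "C"
        seqs[n1:n1 + 2, col] = "C"
        col += 1
    for _ in range(private1):
        seqs[0:2, col] = "C"
        col += 1
    for _ in range(private2):
        seqs[n1:n1 + 2, col] = "C"
        col += 1
    for _ in range(fixed):
        seqs[n1:, col] = "C"
        col += 1
    ids = [f"p1_{i}" for i in range(n1)] + [f"p2_{i}" for i in range(n2)]
    aln = STSAlignment(locus_id, ids, ["".join(r) for r in seqs])
    panel = PopulationPanel({sid: ("pop1" if sid.startswith("p1") else "pop2")
                             for sid in ids})
    return aln, panel


def make_cytotype_panel(frequencies: dict[str, dict[str, float]],
                        n_per_pop: int, seed: int,
                        out_path: str | Path | None = None):
    """Draw cytoplasm marker calls per population from cytotype
    frequencies (rows must sum to 1); returns (records, panel) and
    optionally writes the marker TSV."""
    from .sts_io import CytotypeRecord

    rng = np.random.default_rng(seed)
    records, mapping = [], {}
    for pop, freqs in frequencies.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{pop}: cytotype frequencies sum to {total}, not 1")
        types = list(freqs)
        probs = np.array([freqs[t] for t in types])
        draws = rng.choice(len(types), size=n_per_pop, p=probs)
        for i, d in enumerate(draws):
            sid = f"{pop}_{i:03d}"
            orf, ssv500, ssv39 = types[d].split(".")
            records.append(CytotypeRecord(sid, orf, ssv500, ssv39))
            mapping[sid] = pop
    panel = PopulationPanel(mapping) if mapping else None
    if out_path is not None:
        with open(out_path, "w") as fh:
            for r in records:
                fh.write(f"{r.sample_id}\t{r.orf100}\t{r.ssv500}\t{r.ssv39}\n")
    return records, panel
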