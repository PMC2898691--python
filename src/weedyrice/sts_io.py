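"""Readers, writers and the data model for multi-locus STS panels.

An STS (sequence-tagged site) panel is a set of short (~400-900 bp) aligned
sequence fragments, one FASTA file per locus, sampled as one haplotype per
accession. This module parses those alignments together with a
sample-to-population map, optional per-column site-class annotations
(noncoding / synonymous / nonsynonymous) and optional cytoplasm
(chloroplast + mitochondrial indel) marker calls, and reduces them to a
biallelic 0/1 SNP matrix suitable for diversity and differentiation
statistics.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STSAlignment",
    "PopulationPanel",
    "CytotypeRecord",
    "SNPMatrix",
    "SITE_CLASSES",
    "read_sts_fasta",
    "write_sts_fasta",
    "read_population_map",
    "write_population_map",
    "read_site_classes",
    "read_cytotype_markers",
    "classify_site",
    "build_snp_matrix",
    "combine_cytotype",
    "cytotype_frequencies",
]

SITE_CLASSES = ("noncoding", "synonymous", "nonsynonymous", "unclassified")

#: "silent" variation pools synonymous and noncoding sites.
SILENT_CLASSES = ("noncoding", "synonymous")

_VALID_RESIDUES = set("ACGT-N")

# Two-or-more-base ambiguity codes; heterozygous calls in a haploid panel.
_IUPAC_AMBIGUOUS = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


class AlignmentError(ValueError):
    """Raised when sequences within one locus violate alignment invariants."""


class InputError(ValueError):
    """Raised for malformed or empty input files."""


class LabelingError(KeyError):
    """Raised when a sample lacks a population assignment."""


@dataclass
class STSAlignment:
    """One aligned STS locus: equal-length haplotype sequences over ACGT-N.

    ``site_classes``, when present, labels every alignment column with one of
    :data:`SITE_CLASSES`.
    """

    locus_id: str
    sample_ids: list[str]
    sequences: list[str]
    site_classes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError(
                f"{self.locus_id}: {len(self.sample_ids)} ids but "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError(f"{self.locus_id}: duplicate sample ids")
        if not self.sequences:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if self.site_classes is not None:
            if len(self.site_classes) != self.length_bp:
                raise AlignmentError(
                    f"{self.locus_id}: {len(self.site_classes)} site classes "
                    f"for {self.length_bp} columns"
                )
            bad = set(self.site_classes) - set(SITE_CLASSES)
            if bad:
                raise AlignmentError(f"{self.locus_id}: unknown site classes {bad}")

    @property
    def length_bp(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_array(self) -> np.ndarray:
        """Return the alignment as a (samples, columns) array of 1-char strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


class PopulationPanel:
    """Mapping from sample id to population label."""

    def __init__(self, mapping: Mapping[str, str]):
        for sid, pop in mapping.items():
            if not pop:
                raise InputError(f"empty population label for sample {sid!r}")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._map

    def __getitem__(self, sample_id: str) -> str:
        try:
            return self._map[sample_id]
        except KeyError:
            raise LabelingError(f"sample {sample_id!r} has no population label")

    def items(self):
        return self._map.items()

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self._map.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self._map.items() if p == population]


@dataclass
class CytotypeRecord:
    """Combined state of the Orf100 (chloroplast) and SSV500/SSV39
    (mitochondrial) indel markers for one accession.

    Each marker is scored D (deletion allele) or N (no deletion); the three
    states joined with dots form the cytotype, a maternally inherited
    haplotype. Any missing marker leaves the cytotype undefined.
    """

    sample_id: str
    orf100: str
    ssv500: str
    ssv39: str

    _MISSING = {"missing", ".", "", "NA", "-"}

    def __post_init__(self) -> None:
        norm = []
        for val in (self.orf100, self.ssv500, self.ssv39):
            v = str(val).strip()
            if v in self._MISSING:
                norm.append("missing")
            elif v.upper() in ("D", "N"):
                norm.append(v.upper())
            else:
                raise InputError(
                    f"{self.sample_id}: unknown cytoplasm marker state {val!r}"
                )
        self.orf100, self.ssv500, self.ssv39 = norm

    @property
    def is_defined(self) -> bool:
        return "missing" not in (self.orf100, self.ssv500, self.ssv39)

    @property
    def cytotype(self) -> str | None:
        if not self.is_defined:
            return None
        return f"{self.orf100}.{self.ssv500}.{self.ssv39}"


@dataclass
class SNPMatrix:
    """Biallelic SNPs (rows) by haploid samples (columns), coded 0/1/-1.

    0 is the major allele among the targeted groups, 1 the minor, -1 missing
    (no call, third allele, or heterozygous call treated as missing).

    Attributes
    ----------
    genotypes : int8 array, shape (n_sites, n_samples)
    sites : DataFrame with locus_id, column (0-based), site_class, major, minor
    samples : DataFrame with sample_id, population
    loci : DataFrame indexed by locus_id with length_bp and per-class counts
        of non-indel alignment columns (the per-kb denominators).
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for locus, grp in self.sites.groupby("locus_id", sort=False):
            cols = grp["column"].to_numpy()
            if np.any(np.diff(cols) <= 0):
                raise ValueError(f"{locus}: site columns not strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | Iterable[str]) -> np.ndarray:
        pops = {population} if isinstance(population, str) else set(population)
        idx = np.flatnonzero(self.samples["population"].isin(pops).to_numpy())
        if idx.size == 0:
            raise LabelingError(f"no samples with population label(s) {sorted(pops)}")
        return idx

    def class_mask(self, site_class: str) -> np.ndarray:
        """Boolean mask over sites for 'all', 'silent', or one concrete class."""
        cls = self.sites["site_class"].to_numpy()
        if site_class == "all":
            return np.ones(self.n_sites, dtype=bool)
        if site_class == "silent":
            return np.isin(cls, SILENT_CLASSES)
        if site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {site_class!r}")
        return cls == site_class

    def class_length(self, locus_id: str, site_class: str) -> int:
        """Non-indel column count of the class at one locus (per-kb denominator)."""
        row = self.loci.loc[locus_id]
        if site_class == "all":
            return int(row["n_all"])
        if site_class == "silent":
            return int(row["n_noncoding"] + row["n_synonymous"])
        if site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {site_class!r}")
        return int(row[f"n_{site_class}"])


# ---------------------------------------------------------------------------
# FASTA and TSV readers / writers


def read_sts_fasta(path: str | Path, locus_id: str | None = None) -> STSAlignment:
    """Read one locus alignment from FASTA; residues are uppercased and any
    character outside ACGT-N (including IUPAC ambiguity codes) is kept as-is
    only if ambiguous, otherwise mapped to N."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = []
    for r in records:
        s = str(r.seq).upper()
        s = "".join(
            c if (c in _VALID_RESIDUES or c in _IUPAC_AMBIGUOUS) else "N" for c in s
        )
        seqs.append(s)
    return STSAlignment(locus_id or path.stem, ids, seqs)


def write_sts_fasta(alignment: STSAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(alignment.sample_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_population_map(path: str | Path) -> PopulationPanel:
    """TSV: sample_id <TAB> population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                     dtype=str, comment="#")
    if df.empty:
        raise InputError(f"{path}: empty population map")
    return PopulationPanel(dict(zip(df["sample_id"], df["population"])))


def write_population_map(panel: PopulationPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, pop in panel.items():
            fh.write(f"{sid}\t{pop}\n")


def read_site_classes(path: str | Path) -> dict[str, dict[int, str]]:
    """TSV: locus_id <TAB> column (0-based) <TAB> class; returns nested dict."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["locus_id", "column", "site_class"], comment="#")
    out: dict[str, dict[int, str]] = {}
    for row in df.itertuples(index=False):
        if row.site_class not in SITE_CLASSES:
            raise InputError(f"unknown site class {row.site_class!r}")
        out.setdefault(str(row.locus_id), {})[int(row.column)] = row.site_class
    return out


def attach_site_classes(
    alignment: STSAlignment, classes: Mapping[str, Mapping[int, str]]
) -> STSAlignment:
    """Return a copy of *alignment* with per-column classes applied;
    unannotated columns become 'unclassified'."""
    per_col = classes.get(alignment.locus_id, {})
    labels = [per_col.get(i, "unclassified") for i in range(alignment.length_bp)]
    return STSAlignment(
        alignment.locus_id, list(alignment.sample_ids),
        list(alignment.sequences), labels,
    )


def read_cytotype_markers(path: str | Path) -> list[CytotypeRecord]:
    """TSV: sample_id <TAB> orf100 <TAB> ssv500 <TAB> ssv39."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["sample_id", "orf100", "ssv500", "ssv39"],
                     dtype=str, comment="#", keep_default_na=False)
    if df.empty:
        raise InputError(f"{path}: empty cytoplasm marker file")
    return [
        CytotypeRecord(r.sample_id, r.orf100, r.ssv500, r.ssv39)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Site classification from codons


def classify_site(codon_before: str, codon_after: str) -> str:
    """Classify a single-base codon change as synonymous or nonsynonymous
    under the standard genetic code.

    Raises ``ValueError`` unless the codons differ at exactly one position;
    a change creating or destroying a stop codon is classified (stop != stop
    is nonsynonymous) but reported with a warning.
    """
    a, b = codon_before.upper(), codon_after.upper()
    for codon in (a, b):
        if len(codon) != 3 or any(c not in "ACGT" for c in codon):
            raise ValueError(f"not an unambiguous codon: {codon!r}")
    ndiff = sum(x != y for x, y in zip(a, b))
    if ndiff != 1:
        raise ValueError(f"codons {a}->{b} differ at {ndiff} positions, expected 1")
    aa_a = str(Seq(a).translate())
    aa_b = str(Seq(b).translate())
    if "*" in (aa_a, aa_b):
        warnings.warn(f"stop codon involved in {a}->{b}", stacklevel=2)
    return "synonymous" if aa_a == aa_b else "nonsynonymous"


# ---------------------------------------------------------------------------
# SNP matrix construction


def _resolve_heterozygotes(
    arr: np.ndarray, policy: str, rng: random.Random | None
) -> np.ndarray:
    """Collapse IUPAC ambiguity codes to a single haploid call.

    policy 'missing' turns them into N; 'first' takes the alphabetically
    first base of the code; 'random' picks uniformly (seeded)."""
    out = arr.copy()
    for code, bases in _IUPAC_AMBIGUOUS.items():
        hits = np.argwhere(out == code)
        for i, j in hits:
            if policy == "missing":
                out[i, j] = "N"
            elif policy == "first":
                out[i, j] = bases[0]
            elif policy == "random":
                if rng is None:
                    raise ValueError("policy 'random' requires a seeded rng")
                out[i, j] = rng.choice(bases)
            else:
                raise ValueError(f"unknown heterozygote policy {policy!r}")
    return out


def build_snp_matrix(
    alignments: Sequence[STSAlignment],
    panel: PopulationPanel,
    targeted_groups: Iterable[str],
    het_policy: str = "missing",
    het_seed: int | None = None,
) -> SNPMatrix:
    """Reduce locus alignments to a biallelic 0/1 SNP matrix.

    Columns touching an alignment gap are discarded entirely (indel regions
    carry no SNPs here). Within the samples of ``targeted_groups`` a column is
    retained only when exactly two bases are observed; columns with three or
    more alleles among targeted samples are excluded, but extra alleles
    confined to non-targeted (e.g. outgroup) samples do not remove a site.
    Code 0 is the major allele among targeted samples, ties broken by
    alphabetical order; any other residue is missing (-1).
    """
    targeted = set(targeted_groups)
    rng = random.Random(het_seed) if het_policy == "random" else None

    # stable sample order: first appearance across loci
    sample_order: dict[str, int] = {}
    for aln in alignments:
        for sid in aln.sample_ids:
            if sid not in panel:
                raise LabelingError(f"sample {sid!r} has no population label")
            sample_order.setdefault(sid, len(sample_order))
    all_samples = list(sample_order)
    n_total = len(all_samples)

    geno_blocks: list[np.ndarray] = []
    site_rows: list[dict] = []
    loci_rows: list[dict] = []

    for aln in alignments:
        arr = _resolve_heterozygotes(aln.to_array(), het_policy, rng)
        col_idx = {sid: k for k, sid in enumerate(aln.sample_ids)}
        present = [sid in col_idx for sid in all_samples]
        row_of = np.array([col_idx.get(sid, -1) for sid in all_samples])
        targeted_rows = np.array(
            [col_idx[sid] for sid in aln.sample_ids if panel[sid] in targeted],
            dtype=int,
        )
        classes = aln.site_classes or ["unclassified"] * aln.length_bp

        class_counts = dict.fromkeys(SITE_CLASSES, 0)
        for j in range(aln.length_bp):
            col = arr[:, j]
            if "-" in col:
                continue  # indel column: excluded from sites and denominators
            class_counts[classes[j]] += 1
            if targeted_rows.size == 0:
                continue
            tcol = col[targeted_rows]
            obs = sorted(set(tcol) - {"N"})
            if len(obs) != 2:
                continue
            counts = {b: int(np.sum(tcol == b)) for b in obs}
            # major first; alphabetical order breaks a 50/50 tie
            major, minor = sorted(obs, key=lambda b: (-counts[b], b))
            codes = np.full(n_total, -1, dtype=np.int8)
            for k, sid in enumerate(all_samples):
                if not present[k]:
                    continue
                base = col[row_of[k]]
                if base == major:
                    codes[k] = 0
                elif base == minor:
                    codes[k] = 1
            geno_blocks.append(codes)
            site_rows.append({
                "locus_id": aln.locus_id, "column": j,
                "site_class": classes[j], "major": major, "minor": minor,
            })
        loci_rows.append({
            "locus_id": aln.locus_id, "length_bp": aln.length_bp,
            "n_all": sum(class_counts.values()),
            **{f"n_{c}": class_counts[c] for c in SITE_CLASSES},
        })

    genotypes = (
        np.array(geno_blocks, dtype=np.int8)
        if geno_blocks else np.empty((0, n_total), dtype=np.int8)
    )
    sites = pd.DataFrame(
        site_rows, columns=["locus_id", "column", "site_class", "major", "minor"]
    )
    samples = pd.DataFrame({
        "sample_id": all_samples,
        "population": [panel[s] for s in all_samples],
    })
    loci = pd.DataFrame(loci_rows).set_index("locus_id")
    return SNPMatrix(genotypes, sites, samples, loci)


# ---------------------------------------------------------------------------
# Cytotypes


def combine_cytotype(
    records: Sequence[CytotypeRecord] | Sequence[tuple[str, str, str, str]],
) -> list[CytotypeRecord]:
    """Normalize raw per-marker calls into :class:`CytotypeRecord` objects.

    Maternal inheritance of both organellar genomes is assumed, so the three
    marker states form a single non-recombining haplotype."""
    out = []
    for rec in records:
        if isinstance(rec, CytotypeRecord):
            out.append(rec)
        else:
            out.append(CytotypeRecord(*rec))
    return out


def cytotype_frequencies(
    records: Sequence[CytotypeRecord], panel: PopulationPanel
) -> pd.DataFrame:
    """Population x cytotype frequency table; rows sum to 1 over defined
    cytotypes. Records with an undefined cytotype are excluded from the
    denominator; populations with no defined cytotype are omitted with a
    warning."""
    rows = []
    for rec in records:
        if rec.sample_id not in panel:
            raise LabelingError(f"sample {rec.sample_id!r} has no population label")
        if rec.is_defined:
            rows.append({"population": panel[rec.sample_id], "cytotype": rec.cytotype})
    seen_pops = {panel[rec.sample_id] for rec in records}
    df = pd.DataFrame(rows, columns=["population", "cytotype"])
    counted = df.groupby(["population", "cytotype"]).size().unstack(fill_value=0)
    for pop in sorted(seen_pops - set(counted.index)):
        warnings.warn(f"population {pop!r} has no defined cytotypes; omitted",
                      stacklevel=2)
    freqs = counted.div(counted.sum(axis=1), axis=0)
    return freqs
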