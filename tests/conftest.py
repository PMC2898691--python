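import numpy as np
import pandas as pd
import pytest

from weedyrice.sts_io import SNPMatrix


def matrix_from_arrays(genotypes, populations, locus_sizes=None,
                       site_classes=None):
    """Build an SNPMatrix directly from a (sites x samples) 0/1/-1 array.

    ``locus_sizes`` maps locus_id -> (n_sites, length_bp); default is one
    locus 'L0' of length 1000 holding every site.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape
    if locus_sizes is None:
        locus_sizes = {"L0": (n_sites, 1000)}
    classes = list(site_classes) if site_classes is not None else \
        ["unclassified"] * n_sites
    site_rows, loci_rows = [], []
    k = 0
    for locus, (count, length) in locus_sizes.items():
        counts = dict.fromkeys(
            ("noncoding", "synonymous", "nonsynonymous", "unclassified"), 0)
        for j in range(count):
            site_rows.append({"locus_id": locus, "column": j,
                              "site_class": classes[k], "major": "A",
                              "minor": "C"})
            k += 1
        # whole locus length attributed to 'unclassified' unless site classes
        # are explicitly supplied, in which case split evenly for test use
        if site_classes is None:
            counts["unclassified"] = length
        else:
            uniq = sorted(set(classes[k - count:k]))
            per = length // len(uniq)
            for i, c in enumerate(uniq):
                counts[c] = per if i < len(uniq) - 1 else length - per * (
                    len(uniq) - 1)
        loci_rows.append({"locus_id": locus, "length_bp": length,
                          "n_all": length,
                          **{f"n_{c}": v for c, v in counts.items()}})
    sites = pd.DataFrame(
        site_rows,
        columns=["locus_id", "column", "site_class", "major", "minor"])
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "population": list(populations),
    })
    loci = pd.DataFrame(loci_rows).set_index("locus_id")
    return SNPMatrix(genotypes, sites, samples, loci)


@pytest.fixture
def rng():
    return np.random.default_rng(20090831)


def random_matrix(rng, n_sites=None, n1=None, n2=None, missing=False):
    """Random two-population 0/1 matrix for property tests."""
    n_sites = n_sites if n_sites is not None else int(rng.integers(1, 12))
    n1 = n1 or int(rng.integers(2, 7))
    n2 = n2 or int(rng.integers(2, 7))
    g = rng.integers(0, 2, size=(n_sites, n1 + n2)).astype(np.int8)
    if missing:
        drop = rng.random(g.shape) < 0.1
        g[drop] = -1
    return matrix_from_arrays(g, ["pop1"] * n1 + ["pop2"] * n2), n1, n2
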