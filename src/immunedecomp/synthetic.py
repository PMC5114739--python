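"""Synthetic data generators for every input the pipeline consumes.

Four generators emulate the study conditions of the analysis:

* reference expression profiles in which each immune cell type overexpresses
  its own signature genes over a shared log-normal baseline, plus one
  CD45-negative (non-immune) profile with no overexpression;
* known-proportion linear mixtures of those profiles with signal-to-noise
  scaled Gaussian noise (an S:1 noise level adds noise with per-gene sd
  equal to the clean value divided by S);
* expression cohorts with three planted immune-infiltration classes;
* methylation beta-value cohorts that follow the two-component mixture
  assumption (tumor beta = f * leukocyte beta + (1 - f) * cancer beta).

Mixing proportions are drawn with the uniform-spacings construction: the k
gaps cut from [0, 1] by k-1 sorted Uniform(0,1) draws, i.e. a flat
Dirichlet(1, ..., 1) sample.  All generators take a seeded
``numpy.random.Generator`` and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import SignatureCollection, builtin_signatures, APM_GENES
from .aggregates import TIS_CONSTITUENTS

__all__ = [
    "DEFAULT_CELL_MAP",
    "DEFAULT_SNR_GRID",
    "ReferenceProfiles",
    "MixtureExperiment",
    "SyntheticBetaCohort",
    "simulate_mixing_proportions",
    "make_reference_profiles",
    "mix_and_add_noise",
    "make_clustered_cohort",
    "make_methylation_cohort",
]

#: Immune cell type -> scoring signature, as used in the mixture experiment.
DEFAULT_CELL_MAP = {
    "macrophage": "Macrophages",
    "NK": "NK cells",
    "CD8_T": "CD8 T cells",
    "CD4_T": "T helper cells",
}

#: S values of the default S:1 noise sweep; both reported "extremely noisy"
#: endpoints (1:1 and 1:2) are included.
DEFAULT_SNR_GRID = (10, 9, 8, 7, 6, 5, 4, 3, 2, 1, 0.5)

DEFAULT_N_GENES = 20_032


@dataclass(frozen=True)
class ReferenceProfiles:
    """Mean expression per (gene, cell type); genes x cell types."""

    values: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MixtureExperiment:
    """A known-proportion in silico mixture.

    proportions: samples x cell types, rows summing to 1 (the truth).
    mixture: genes x samples expression, possibly noisy (not clipped at 0).
    snr: the S of the S:1 noise level, or None for the clean dataset.
    """

    proportions: pd.DataFrame
    mixture: pd.DataFrame
    snr: float | None

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]


def _spacings(u: np.ndarray) -> np.ndarray:
    """Map sorted-or-not uniforms (n, k-1) to the k spacings they cut in [0,1]."""
    u = np.sort(np.atleast_2d(u), axis=1)
    n = u.shape[0]
    bounded = np.hstack([np.zeros((n, 1)), u, np.ones((n, 1))])
    return np.diff(bounded, axis=1)


def simulate_mixing_proportions(
    n_samples: int, k: int = 5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw (n_samples, k) mixing proportions via uniform spacings.

    Each row: sort k-1 U(0,1) draws and return the k consecutive gaps
    (first value; differences; 1 minus the largest).  Rows sum to 1 and are
    marginally Beta(1, k-1), i.e. a flat Dirichlet.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = rng or np.random.default_rng()
    return _spacings(rng.random((n_samples, k - 1)))


def make_reference_profiles(
    collection: SignatureCollection | None = None,
    cell_map: dict[str, str] | None = None,
    p: int = DEFAULT_N_GENES,
    fold: float = 5.0,
    baseline: tuple[float, float] = (3.0, 1.0),
    rng: np.random.Generator | None = None,
    non_immune_label: str = "CD45neg",
) -> ReferenceProfiles:
    """Build per-cell-type mean expression vectors over a p-gene universe.

    A shared baseline is drawn once per gene from a log-normal distribution
    (``baseline`` = (meanlog, sdlog), mimicking normalized RNA-Seq scale);
    each immune cell type then overexpresses its own signature genes by
    ``fold``.  The non-immune profile overexpresses nothing.  Signatures
    assigned to different cell types must be pairwise gene-disjoint.

    The gene universe contains *every* gene of ``collection`` (so that any
    of its signatures can later be scored on mixtures, as on a real
    transcriptome) padded with synthetic filler genes up to ``p``.
    """
    rng = rng or np.random.default_rng()
    collection = collection or builtin_signatures("bindea24")
    cell_map = dict(cell_map or DEFAULT_CELL_MAP)
    if fold <= 0:
        raise ValueError("fold must be > 0")

    sig_genes: dict[str, tuple[str, ...]] = {}
    for cell_type, sig_name in cell_map.items():
        sig_genes[cell_type] = collection[sig_name].genes
    cells = list(cell_map)
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            shared = set(sig_genes[a]) & set(sig_genes[b])
            if shared:
                raise ValueError(
                    f"signatures for {a!r} and {b!r} share genes: {sorted(shared)}"
                )

    mapped_genes = [g for c in cells for g in sig_genes[c]]
    other_genes = sorted(
        {g for sig in collection for g in sig.genes} - set(mapped_genes)
    )
    signature_universe = mapped_genes + other_genes
    n_filler = p - len(signature_universe)
    if n_filler < 0:
        raise ValueError(f"p={p} smaller than the {len(signature_universe)} signature genes")
    filler = [f"GENE{i:05d}" for i in range(n_filler)]
    genes = pd.Index(signature_universe + filler, name="gene")

    meanlog, sdlog = baseline
    base = rng.lognormal(meanlog, sdlog, size=p)
    values = pd.DataFrame(
        np.tile(base[:, None], (1, len(cells) + 1)),
        index=genes,
        columns=cells + [non_immune_label],
    )
    for cell_type in cells:
        values.loc[list(sig_genes[cell_type]), cell_type] *= fold
    return ReferenceProfiles(values)


def mix_and_add_noise(
    refs: ReferenceProfiles,
    proportions: np.ndarray | pd.DataFrame,
    snr: float | None = None,
    rng: np.random.Generator | None = None,
) -> MixtureExperiment:
    """Linearly combine reference profiles and optionally inject S:1 noise.

    clean(g, i) = sum_c proportions[i, c] * refs(g, c); at noise level S the
    noise sd per (gene, sample) is clean/S.  Noisy values may go negative —
    rank-based scoring downstream does not require flooring.
    """
    if isinstance(proportions, pd.DataFrame):
        if list(proportions.columns) != refs.cell_types:
            raise ValueError("proportion columns do not match reference cell types")
        prop = proportions.to_numpy(dtype=float)
        sample_ids = proportions.index
    else:
        prop = np.asarray(proportions, dtype=float)
        sample_ids = pd.RangeIndex(prop.shape[0], name="sample")
    if prop.ndim != 2 or prop.shape[1] != len(refs.cell_types):
        raise ValueError(
            f"proportions must be (n_samples, {len(refs.cell_types)})"
        )
    if snr is not None and snr <= 0:
        raise ValueError("snr must be > 0 or None")

    clean = refs.values.to_numpy() @ prop.T
    if snr is None:
        mixed = clean
    else:
        rng = rng or np.random.default_rng()
        mixed = clean + rng.normal(0.0, 1.0, size=clean.shape) * (clean / snr)
    mixture = pd.DataFrame(
        mixed, index=refs.gene_ids, columns=[f"S{i:03d}" for i in range(prop.shape[0])]
    )
    prop_df = pd.DataFrame(prop, index=mixture.columns, columns=refs.cell_types)
    prop_df.index.name = "sample"
    return MixtureExperiment(proportions=prop_df, mixture=mixture, snr=snr)


def make_clustered_cohort(
    n_per_class: tuple[int, int, int] = (30, 60, 30),
    collection: SignatureCollection | None = None,
    effect: float = 2.0,
    rng: np.random.Generator | None = None,
    p: int = 8000,
    baseline: tuple[float, float] = (3.0, 1.0),
    sample_sdlog: float = 0.35,
    het_range: tuple[float, float] = (0.25, 0.75),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression cohort with three planted immune-infiltration classes.

    Class 1 ("T cell enriched") overexpresses the union of the nine T-cell
    subset signatures, the APM genes and the checkpoint-target genes by
    2**effect; class 2 ("heterogeneously infiltrated") overexpresses the
    angiogenesis genes by 2**effect and scales the same immune genes by a
    per-sample 2**(effect * u), u ~ U(*het_range*) — intermediate,
    sample-varying infiltration rather than the all-or-nothing of classes
    1 and 3; class 3 is baseline.  A log-normal per-(gene, sample) factor
    (sdlog ``sample_sdlog``) supplies within-class variability.  Returns
    (genes x samples matrix, true labels 1/2/3 per sample).
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = rng or np.random.default_rng()
    collection = collection or builtin_signatures("bindea24")

    t_cell_genes: set[str] = set()
    for name in TIS_CONSTITUENTS:
        t_cell_genes |= set(collection[name].genes)
    immune_genes = t_cell_genes | set(APM_GENES) | {"PDCD1", "CD274", "CTLA4"}
    angio_genes = set(builtin_signatures("angiogenesis")["Angiogenesis"].genes)

    panel_genes = sorted(
        {g for sig in collection for g in sig.genes} | immune_genes | angio_genes
    )
    n_filler = p - len(panel_genes)
    if n_filler < 0:
        raise ValueError(f"p={p} smaller than the {len(panel_genes)} panel genes")
    genes = pd.Index(panel_genes + [f"GENE{i:05d}" for i in range(n_filler)], name="gene")

    n1, n2, n3 = n_per_class
    n = n1 + n2 + n3
    labels = np.repeat([1, 2, 3], [n1, n2, n3])
    base = rng.lognormal(*baseline, size=len(genes))

    log2_shift = np.zeros((len(genes), n))
    immune_rows = genes.get_indexer([g for g in genes if g in immune_genes])
    angio_rows = genes.get_indexer([g for g in genes if g in angio_genes])
    log2_shift[np.ix_(immune_rows, np.flatnonzero(labels == 1))] = effect
    het = np.flatnonzero(labels == 2)
    log2_shift[np.ix_(angio_rows, het)] = effect
    log2_shift[np.ix_(immune_rows, het)] = (
        effect * rng.uniform(*het_range, size=len(het))[None, :]
    )

    noise = rng.lognormal(0.0, sample_sdlog, size=(len(genes), n))
    values = base[:, None] * (2.0 ** log2_shift) * noise
    expr = pd.DataFrame(values, index=genes,
                        columns=[f"P{i:03d}" for i in range(n)])
    return expr, labels


@dataclass(frozen=True)
class SyntheticBetaCohort:
    """Methylation cohort with known leukocyte fractions.

    tumor_betas / leukocyte_reference_betas are probe x sample frames of
    beta values in [0, 1]; true_fractions holds one leukocyte fraction per
    tumor sample.
    """

    tumor_betas: pd.DataFrame
    leukocyte_reference_betas: pd.DataFrame
    true_fractions: pd.Series
    #: latent per-probe compartment levels (generator truth, for diagnostics)
    latent_leukocyte: pd.Series | None = None
    latent_cancer: pd.Series | None = None

    @property
    def probe_ids(self) -> pd.Index:
        return self.tumor_betas.index


def make_methylation_cohort(
    n_tumors: int,
    n_probes: int,
    true_fractions,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    n_ref: int = 6,
    frac_informative: float = 0.4,
    ref_noise_sd: float = 0.02,
) -> SyntheticBetaCohort:
    """Beta-value mixtures tumor = f*B + (1-f)*C + noise, clipped to [0,1].

    Leukocyte (B_k) and cancer (C_k) probe levels are drawn with a bimodal
    separation: a ``frac_informative`` share of probes is strongly
    differentially methylated (half leukocyte-high, half leukocyte-low,
    separation 0.4-0.8 beta units) and the rest is uninformative.  The
    leukocyte reference frame emulates ``n_ref`` healthy-donor profiles
    (B_k plus small Gaussian wobble).  At least 2000 probes are required so
    that the top+bottom-1000 signature construction downstream is possible.
    """
    if n_probes < 2000:
        raise ValueError("n_probes must be >= 2000 (top+bottom 1000 construction)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f = np.asarray(true_fractions, dtype=float)
    if f.shape != (n_tumors,):
        raise ValueError("true_fractions must have one value per tumor sample")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("true fractions must lie in [0, 1]")
    rng = rng or np.random.default_rng()

    n_info = int(round(frac_informative * n_probes))
    n_hi = n_info // 2
    b = np.empty(n_probes)
    c = np.empty(n_probes)
    if n_info:
        sep = rng.uniform(0.4, 0.8, size=n_info)
        low_level = rng.uniform(0.05, 0.95 - sep.max(), size=n_info)
        # leukocyte-high probes
        b[:n_hi] = low_level[:n_hi] + sep[:n_hi]
        c[:n_hi] = low_level[:n_hi]
        # leukocyte-low probes
        b[n_hi:n_info] = low_level[n_hi:]
        c[n_hi:n_info] = low_level[n_hi:] + sep[n_hi:]
    # uninformative probes: near-identical compartments
    rest = n_probes - n_info
    shared = rng.uniform(0.1, 0.9, size=rest)
    b[n_info:] = np.clip(shared + rng.normal(0, 0.01, rest), 0, 1)
    c[n_info:] = np.clip(shared + rng.normal(0, 0.01, rest), 0, 1)

    probes = pd.Index([f"cg{i:07d}" for i in range(n_probes)], name="probe")
    ref = np.clip(
        b[:, None] + rng.normal(0, ref_noise_sd, size=(n_probes, n_ref)), 0, 1
    )
    tumor = b[:, None] * f[None, :] + c[:, None] * (1 - f[None, :])
    if noise_sd > 0:
        tumor = tumor + rng.normal(0, noise_sd, size=tumor.shape)
    tumor = np.clip(tumor, 0, 1)

    tumor_ids = [f"T{i:03d}" for i in range(n_tumors)]
    return SyntheticBetaCohort(
        tumor_betas=pd.DataFrame(tumor, index=probes, columns=tumor_ids),
        leukocyte_reference_betas=pd.DataFrame(
            ref, index=probes, columns=[f"PBMC{i}" for i in range(n_ref)]
        ),
        true_fractions=pd.Series(f, index=tumor_ids, name="leukocyte_fraction"),
        latent_leukocyte=pd.Series(b, index=probes, name="B_k"),
        latent_cancer=pd.Series(c, index=probes, name="C_k"),
    )
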