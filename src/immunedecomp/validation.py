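"""Mixture-recovery validation: Spearman recovery and bootstrap nulls.

The harness asks whether ssGSEA scores recover *known* mixing proportions
from in silico cell mixtures.  For each mapped immune cell type the
Spearman correlation between the true proportion column and the ssGSEA
score row is the recovery estimate; its significance comes from an
empirical null built by scoring size-matched random gene signatures (drawn
uniformly without replacement from the matrix gene universe) on the same
mixture, with

    p = #(null rho >= observed rho) / n_draws.

`run_snr_sweep` repeats this over the clean dataset and a grid of S:1
noise levels, drawing fresh proportions per level, and returns one tidy
record per (cell type, noise level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .signatures import SignatureCollection, builtin_signatures
from .ssgsea import RankedExpression, SsgseaParams
from .synthetic import (
    DEFAULT_CELL_MAP,
    DEFAULT_SNR_GRID,
    MixtureExperiment,
    ReferenceProfiles,
    mix_and_add_noise,
    simulate_mixing_proportions,
)

__all__ = [
    "NullDistribution",
    "recovery_correlations",
    "random_signature_null",
    "bootstrap_pvalue",
    "run_snr_sweep",
]


@dataclass(frozen=True)
class NullDistribution:
    """Spearman correlations of size-matched random signatures vs the truth."""

    cell_type: str
    signature_size: int
    correlations: np.ndarray

    @property
    def n_draws(self) -> int:
        return len(self.correlations)


def _ranked(experiment: MixtureExperiment) -> RankedExpression:
    return RankedExpression(experiment.mixture)


def recovery_correlations(
    experiment: MixtureExperiment,
    collection: SignatureCollection | None = None,
    cell_map: dict[str, str] | None = None,
    params: SsgseaParams | None = None,
    ranked: RankedExpression | None = None,
) -> pd.Series:
    """Per-cell-type Spearman rho between true proportions and ssGSEA scores.

    Only cell types in ``cell_map`` are scored (the non-immune compartment
    has no signature and no rho).  Normalization is irrelevant here —
    Spearman is invariant to the global rescaling — so raw scores are used.
    """
    if experiment.n_samples < 3:
        raise ValueError("need at least 3 samples for a Spearman correlation")
    collection = collection or builtin_signatures("bindea24")
    cell_map = dict(cell_map or DEFAULT_CELL_MAP)
    params = params or SsgseaParams()
    ranked = ranked or _ranked(experiment)

    rhos = {}
    for cell_type, sig_name in cell_map.items():
        rows = ranked.gene_locations(collection[sig_name].genes)
        if len(rows) == 0:
            raise ValueError(f"signature {sig_name!r} has no genes in matrix")
        scores = ranked.es(rows, params.alpha)
        truth = experiment.proportions[cell_type].to_numpy()
        rhos[cell_type] = float(spearmanr(truth, scores).statistic)
    return pd.Series(rhos, name="spearman_rho")


def random_signature_null(
    experiment: MixtureExperiment,
    cell_type: str,
    signature_size: int,
    n_draws: int = 1000,
    params: SsgseaParams | None = None,
    rng: np.random.Generator | None = None,
    ranked: RankedExpression | None = None,
) -> NullDistribution:
    """Null recovery correlations from random signatures of matched size.

    Each draw picks ``signature_size`` genes uniformly without replacement
    from the mixture's gene universe, scores them, and records the Spearman
    rho against the true proportions of ``cell_type``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    params = params or SsgseaParams()
    rng = rng or np.random.default_rng()
    ranked = ranked or _ranked(experiment)
    p = ranked.p
    if signature_size >= p:
        raise ValueError(f"signature_size must be < {p} (gene universe size)")
    truth = experiment.proportions[cell_type].to_numpy()
    truth_ranks = pd.Series(truth).rank().to_numpy()

    correlations = np.empty(n_draws)
    for d in range(n_draws):
        rows = rng.choice(p, size=signature_size, replace=False)
        scores = ranked.es(rows, params.alpha)
        correlations[d] = float(spearmanr(truth_ranks, scores).statistic)
    return NullDistribution(cell_type, signature_size, correlations)


def bootstrap_pvalue(
    observed_rho: float, null: NullDistribution, smoothed: bool = False
) -> float:
    """Fraction of null correlations at least as large as the observed one.

    The plain fraction can be exactly 0; ``smoothed`` switches to the
    (r + 1) / (n + 1) estimator for callers that need a nonzero p.
    """
    if null.n_draws == 0:
        raise ValueError("null distribution is empty")
    r = int(np.sum(null.correlations >= observed_rho))
    if smoothed:
        return (r + 1) / (null.n_draws + 1)
    return r / null.n_draws


def run_snr_sweep(
    refs: ReferenceProfiles,
    collection: SignatureCollection | None = None,
    cell_map: dict[str, str] | None = None,
    snr_grid=DEFAULT_SNR_GRID,
    n_samples: int = 200,
    n_draws: int = 1000,
    params: SsgseaParams | None = None,
    rng: np.random.Generator | None = None,
    include_clean: bool = True,
) -> pd.DataFrame:
    """Full recovery experiment over a noise grid.

    For the clean dataset (snr recorded as inf) and every S in ``snr_grid``:
    draw fresh mixing proportions, build the (noisy) mixture, compute the
    recovery rho per mapped cell type, and attach a bootstrap p from a
    size-matched random-signature null computed on the same mixture.
    Returns a tidy frame (cell_type, snr, rho, p, n_samples, n_draws).
    """
    snr_grid = list(snr_grid)
    if not snr_grid and not include_clean:
        raise ValueError("empty noise grid")
    collection = collection or builtin_signatures("bindea24")
    cell_map = dict(cell_map or DEFAULT_CELL_MAP)
    params = params or SsgseaParams()
    rng = rng or np.random.default_rng()

    levels: list[float | None] = ([None] if include_clean else []) + snr_grid
    records = []
    for snr in levels:
        proportions = simulate_mixing_proportions(
            n_samples, k=len(refs.cell_types), rng=rng
        )
        experiment = mix_and_add_noise(refs, proportions, snr=snr, rng=rng)
        ranked = _ranked(experiment)
        rhos = recovery_correlations(
            experiment, collection, cell_map, params, ranked=ranked
        )
        for cell_type, sig_name in cell_map.items():
            size = len(ranked.gene_locations(collection[sig_name].genes))
            null = random_signature_null(
                experiment, cell_type, size, n_draws, params, rng, ranked=ranked
            )
            records.append(
                {
                    "cell_type": cell_type,
                    "snr": np.inf if snr is None else float(snr),
                    "rho": float(rhos[cell_type]),
                    "p": bootstrap_pvalue(float(rhos[cell_type]), null),
                    "n_samples": n_samples,
                    "n_draws": n_draws,
                }
            )
    return pd.DataFrame.from_records(records)
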