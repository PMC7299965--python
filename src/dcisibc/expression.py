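"""Expression preprocessing: quantile normalization, probe collapsing, and
receptor-status calling from bimodal marker genes.

The expression substrate is a genes x samples DataFrame of log2 intensities.
Receptor status (ER from ESR1, PR from PGR) is called by fitting a
two-component equal-variance Gaussian mixture to the marker gene's values
across the cohort and thresholding at the point of equal posterior
probability between the components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "ReceptorCall",
    "quantile_normalize",
    "collapse_probes",
    "call_receptor_status",
]


@dataclass(frozen=True)
class ReceptorCall:
    sample_id: str
    gene: str
    status: str  # "positive" or "negative"
    cutoff: float
    posterior: float


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes x samples matrix.

    Every sample's sorted value vector is replaced by the across-sample mean
    of sorted vectors. Ties within a sample receive the mean of the reference
    quantiles at their tied ranks, so tied input values stay tied.
    """
    if matrix.isna().any().any():
        raise ValueError(
            "matrix contains missing values; impute before quantile normalization"
        )
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)  # mean quantile profile
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        mapped = ref[rankdata(col, method="ordinal") - 1]
        # tied input values get the mean of the reference quantiles spanned
        # by their tied ranks, so ties stay tied
        out[:, j] = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: pd.Series | dict
) -> pd.DataFrame:
    """Collapse probe rows to one row per gene by arithmetic mean.

    Probes with no gene mapping are dropped (a count is logged).
    """
    mapping = pd.Series(probe_to_gene)
    genes = probe_matrix.index.map(mapping)
    unmapped = genes.isna()
    if unmapped.any():
        logger.warning("dropping %d probes with no gene mapping", int(unmapped.sum()))
    kept = probe_matrix.loc[~unmapped]
    collapsed = kept.groupby(genes[~unmapped]).mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


def _equal_posterior_cutoff(gm: GaussianMixture) -> float:
    """Point where the two equal-variance components have equal posterior:
    the midpoint of the means shifted by the log weight ratio."""
    m = gm.means_.ravel()
    w = gm.weights_
    var = float(np.asarray(gm.covariances_).ravel()[0])
    lo, hi = (0, 1) if m[0] < m[1] else (1, 0)
    return 0.5 * (m[lo] + m[hi]) + var * np.log(w[lo] / w[hi]) / (m[hi] - m[lo])


def call_receptor_status(
    expression_row: pd.Series,
    gene: str = "ESR1",
    *,
    fallback_cutoff: float | None = None,
    random_state: int = 0,
) -> list[ReceptorCall]:
    """Call positive/negative receptor status from one gene's expression.

    Fits a 2-component equal-variance Gaussian mixture (EM, 10 random
    restarts). The cutoff is the equal-posterior point between components;
    a sample is positive iff its value is strictly above the cutoff. If the
    fitted components are separated by less than one (common) standard
    deviation the fit is considered degenerate: a user-supplied
    ``fallback_cutoff`` is used if given, otherwise a "not bimodal" error is
    raised.
    """
    x = expression_row.dropna().astype(float)
    if x.size < 10:
        raise ValueError("receptor calling requires >= 10 samples")
    values = x.to_numpy().reshape(-1, 1)
    cutoff = None
    posterior_of = None
    if np.unique(values).size >= 2:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="tied",
            n_init=10,
            random_state=random_state,
        ).fit(values)
        sd = float(np.sqrt(np.asarray(gm.covariances_).ravel()[0]))
        separation = abs(float(gm.means_[1, 0] - gm.means_[0, 0]))
        if separation >= sd:
            cutoff = float(_equal_posterior_cutoff(gm))
            resp = gm.predict_proba(values)
            high = int(np.argmax(gm.means_.ravel()))

            def posterior_of(i, status):
                comp = high if status == "positive" else 1 - high
                return float(resp[i, comp])

    if cutoff is None:
        if fallback_cutoff is None:
            raise ValueError(f"{gene} expression is not bimodal and no fallback cutoff given")
        warnings.warn(
            f"{gene}: degenerate mixture fit; using fallback cutoff {fallback_cutoff}",
            stacklevel=2,
        )
        cutoff = float(fallback_cutoff)
        posterior_of = lambda i, status: 1.0  # noqa: E731 - hard assignment

    calls = []
    for i, (sample, value) in enumerate(x.items()):
        status = "positive" if value > cutoff else "negative"
        calls.append(
            ReceptorCall(
                sample_id=str(sample),
                gene=gene,
                status=status,
                cutoff=cutoff,
                posterior=posterior_of(i, status),
            )
        )
    return calls


def receptor_calls_to_series(calls: list[ReceptorCall]) -> pd.Series:
    """Convenience: sample -> status Series from a list of calls."""
    return pd.Series({c.sample_id: c.status for c in calls}, name=calls[0].gene)
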