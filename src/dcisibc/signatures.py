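"""Per-sample gene-expression signature scores.

A signature is a list of (gene, weight) entries; its score for a sample is
the mean over the signature's genes of weight x z-score, where z-scores are
computed per gene across the whole cohort. With unit weights this is the
classical mean-Z score (e.g. an 11-gene proliferation score); signed weights
support signatures like an EMT score built from positively weighted EMT
genes and negatively weighted adhesion genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SignatureDef", "zscore_by_gene", "score_signature", "score_signatures"]


@dataclass(frozen=True)
class SignatureDef:
    name: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if len(self.entries) == 0:
            raise ValueError(f"signature {self.name} has no entries")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene ids in signature {self.name}")

    @classmethod
    def from_lists(cls, name, positive, negative=()):
        entries = [(g, 1.0) for g in positive] + [(g, -1.0) for g in negative]
        return cls(name=name, entries=tuple(entries))


def zscore_by_gene(
    matrix: pd.DataFrame, *, ddof: int = 1, drop_constant: bool = False
) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 across samples.

    The sample (n-1) standard deviation is the default. Zero-variance genes
    become rows of zeros with a warning (or are dropped if
    ``drop_constant``), since they carry no signature information.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance genes set to z=0", stacklevel=2
        )
    sd[constant.reshape(-1, 1)] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    if drop_constant:
        out = out.loc[~constant]
    return out


def score_signature(z: pd.DataFrame, sig: SignatureDef) -> tuple[pd.Series, int]:
    """Score one signature: per sample, mean of weight x z over the signature
    genes present in the matrix. Returns (scores, n_genes_found)."""
    present = [(g, w) for g, w in sig.entries if g in z.index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name} found in matrix")
    dropped = len(sig.entries) - len(present)
    if dropped:
        logger.info("signature %s: %d genes not in matrix", sig.name, dropped)
    genes = [g for g, _ in present]
    weights = np.array([w for _, w in present])
    scores = (z.loc[genes].to_numpy(dtype=float) * weights[:, None]).mean(axis=0)
    return pd.Series(scores, index=z.columns, name=sig.name), len(present)


def score_signatures(
    matrix: pd.DataFrame, sigs: list[SignatureDef], *, ddof: int = 1
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score several signatures on a cohort; z-scores computed once over the
    full matrix (all tumor types together). Returns the sample x signature
    score table and the per-signature count of genes found."""
    z = zscore_by_gene(matrix, ddof=ddof)
    cols, found = {}, {}
    for sig in sigs:
        cols[sig.name], found[sig.name] = score_signature(z, sig)
    return pd.DataFrame(cols), found
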