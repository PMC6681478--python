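"""Lineage-grouped principal component analysis of proteome features.

Feature vectors per proteome mix amino-acid fractions (percent-scale)
and pH-unit quantities, so the default scaling is autoscale (center and
divide by sample standard deviation).  The decomposition is a direct
singular-value factorization of the scaled matrix: the inputs are at
most a few hundred proteomes, so an exact deterministic solve is both
feasible and preferable to iterative methods.  Component signs are
fixed by making the largest-magnitude loading of each component
positive.

Influence statistics per row follow chemometrics convention:
Hotelling's T^2 is the within-model leverage, sum over retained
components of score^2 / component variance; the Q residual is the
squared norm of the part of the (scaled) row the retained components do
not reconstruct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profile import ProteomeSummary
from .sequence_io import STANDARD_RESIDUES

SUMMARY_FEATURES = ("pct_acidic", "pct_basic", "avg_acidic_pi", "avg_basic_pi")

_VAR_EPS = 1e-12


def build_feature_matrix(
    summaries: Sequence[ProteomeSummary],
    compositions: Mapping[str, Mapping[str, float]] | None = None,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the proteomes x features matrix.

    ``compositions`` maps species to residue-fraction dicts (as from
    :func:`protpi.profile.proteome_composition`).  ``features`` selects
    and orders columns from the 20 residue letters plus
    ``pct_acidic``, ``pct_basic``, ``avg_acidic_pi``, ``avg_basic_pi``;
    default is all residue fractions followed by the four summary
    features.  Rows are indexed by (species, lineage).
    """
    if features is None:
        features = list(STANDARD_RESIDUES) + list(SUMMARY_FEATURES)
    rows = []
    index = []
    for s in summaries:
        row = {}
        comp = compositions.get(s.species) if compositions else None
        for f in features:
            if f in STANDARD_RESIDUES:
                if comp is None:
                    raise KeyError(
                        f"feature {f!r} requested but no composition given for {s.species!r}"
                    )
                row[f] = comp[f]
            elif f in SUMMARY_FEATURES:
                value = getattr(s, f)
                if value is None:
                    raise ValueError(
                        f"feature {f!r} undefined for {s.species!r} (empty class)"
                    )
                row[f] = value
            else:
                raise KeyError(f"unknown feature {f!r}")
        rows.append(row)
        index.append((s.species, s.lineage))
    m = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["species", "lineage"]))
    return m[list(features)]


@dataclass
class PCAResult:
    """Scores, loadings, variance decomposition and influence statistics."""

    scores: pd.DataFrame                 # rows x components
    loadings: pd.DataFrame               # features x components
    explained_variance: np.ndarray       # score-column variance (ddof=1)
    explained_variance_fraction: np.ndarray
    hotelling_t2: pd.Series
    q_residuals: pd.Series
    n_components: int
    _z: np.ndarray                       # processed matrix (centered/scaled)
    _full_scores: np.ndarray
    _full_loadings: np.ndarray
    _full_variance: np.ndarray


def run_pca(
    m: pd.DataFrame,
    n_components: int | None = None,
    scaling: str = "autoscale",
) -> PCAResult:
    """PCA of a feature matrix by exact SVD.

    ``scaling`` is ``"autoscale"`` (center + unit variance, default) or
    ``"center"`` (center only).  Deterministic, including component
    signs.
    """
    x = m.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("feature matrix must be at least 2 x 2")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    max_components = min(n_rows - 1, n_cols)
    if n_components is None:
        n_components = max_components
    if not 1 <= n_components <= max_components:
        raise ValueError(
            f"n_components must be in [1, {max_components}], got {n_components}"
        )

    z = x - x.mean(axis=0)
    if scaling == "autoscale":
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [m.columns[i] for i in zero]
            raise ValueError(f"zero-variance features cannot be autoscaled: {names}")
        z = z / sd
    elif scaling != "center":
        raise ValueError(f"scaling must be 'autoscale' or 'center', got {scaling!r}")

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k_full = min(n_rows - 1, n_cols)  # rank bound after centering
    u, s, vt = u[:, :k_full], s[:k_full], vt[:k_full]
    scores = u * s
    loadings = vt.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(k_full):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    variance = s**2 / (n_rows - 1)
    total = np.square(z).sum() / (n_rows - 1)
    fraction = variance / total if total > 0 else np.zeros_like(variance)

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores_df = pd.DataFrame(scores[:, :n_components], index=m.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings[:, :n_components], index=m.columns, columns=comp_names)

    result = PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance=variance[:n_components],
        explained_variance_fraction=fraction[:n_components],
        hotelling_t2=pd.Series(dtype=float),
        q_residuals=pd.Series(dtype=float),
        n_components=n_components,
        _z=z,
        _full_scores=scores,
        _full_loadings=loadings,
        _full_variance=variance,
    )
    influence = influence_stats(result, n_components)
    result.hotelling_t2 = influence["hotelling_t2"]
    result.q_residuals = influence["q_residual"]
    return result


def influence_stats(result: PCAResult, retained: int) -> pd.DataFrame:
    """Hotelling T^2 and Q residual per row for a retained-component count.

    Components with (numerically) zero variance contribute nothing to
    T^2; their scores are zero to machine precision anyway.
    """
    if not 1 <= retained <= result._full_scores.shape[1]:
        raise ValueError(
            f"retained must be in [1, {result._full_scores.shape[1]}], got {retained}"
        )
    s = result._full_scores[:, :retained]
    var = result._full_variance[:retained]
    safe = np.where(var > _VAR_EPS, var, np.inf)
    t2 = (s**2 / safe).sum(axis=1)
    recon = s @ result._full_loadings[:, :retained].T
    q = np.square(result._z - recon).sum(axis=1)
    return pd.DataFrame(
        {"hotelling_t2": t2, "q_residual": q}, index=result.scores.index
    )


def lineage_silhouette(result: PCAResult, n_components: int = 2) -> float:
    """Mean silhouette of lineage grouping on the leading score columns."""
    from sklearn.metrics import silhouette_score

    labels = result.scores.index.get_level_values("lineage")
    k = min(n_components, result.scores.shape[1])
    return float(silhouette_score(result.scores.iloc[:, :k].to_numpy(), labels))
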