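"""Cytoband-level CNV concordance across methods and kNN value transfer.

Different CNV callers (expression-based, coverage-based, allele-based)
report on different units — genes, genomic bins, cytobands — so agreement
is assessed at the cytoband level: each method's matrix is scaled to
[-2, 2], averaged per cytoband, and summarized as a duplication/deletion
*effect*: mean over malignant pseudobulks minus mean over normal
pseudobulks.  Effects are rank-correlated (Spearman) between method pairs,
and a cytoband is labeled ``dup_effect``/``del_effect`` only when every
method agrees on the sign; any disagreement (a zero counts as one) yields
``not_correlated``.

``knn_value_transfer`` maps per-cell values (e.g. pseudotime) from one
modality to another through a shared embedding: each query cell receives
the unweighted mean of its k nearest reference cells.  The embedding itself
(CCA, anchors) is consumed, not computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr


@dataclass
class EffectTable:
    """Per-cytoband effects by method, with trend labels and pairwise rho."""

    effects: pd.DataFrame
    labels: Optional[pd.Series] = None
    rho: Optional[pd.DataFrame] = None

    @property
    def n_overlapping_cytobands(self) -> int:
        return len(self.effects)


def _scale(values: pd.DataFrame, limit: float) -> pd.DataFrame:
    max_abs = float(np.abs(values.to_numpy()).max()) if values.size else 0.0
    if max_abs == 0:
        return values
    return values * (limit / max_abs)


def cytoband_effects(
    methods: Mapping[str, tuple],
    labels: Union[pd.Series, Mapping[str, pd.Series]],
    scale_limit: float = 2.0,
) -> EffectTable:
    """Duplication/deletion effect per cytoband for each method.

    ``methods`` maps method name -> (values, cytoband_of_region) where
    ``values`` is regions (genes or bins) x pseudobulks and
    ``cytoband_of_region`` assigns each region row to a cytoband.
    ``labels`` maps pseudobulk -> {"malignant", "normal", ...}, either one
    shared series or one per method.  Per method: scale values to
    [-scale_limit, scale_limit], average regions within each cytoband, then
    subtract the normal-pseudobulk mean from the malignant-pseudobulk mean.
    Only cytobands present in every method are kept.
    """
    if not methods:
        raise ValueError("at least one method required")
    effects = {}
    for name, (values, bands) in methods.items():
        method_labels = labels[name] if isinstance(labels, Mapping) else labels
        method_labels = method_labels.reindex(values.columns)
        mal = values.columns[method_labels == "malignant"]
        nor = values.columns[method_labels == "normal"]
        if mal.empty or nor.empty:
            raise ValueError(f"method {name!r} needs both malignant and normal pseudobulks")
        scaled = _scale(values, scale_limit)
        bands = pd.Series(bands).reindex(values.index)
        per_band = scaled.groupby(bands, sort=True).mean()
        effects[name] = per_band[mal].mean(axis=1) - per_band[nor].mean(axis=1)
    table = pd.DataFrame(effects).dropna()
    if table.empty:
        raise ValueError("no cytoband is shared by all methods")
    return EffectTable(effects=table)


def concordance(table: Union[EffectTable, pd.DataFrame], min_cytobands: int = 3) -> EffectTable:
    """Label cytobands by cross-method trend and compute pairwise Spearman rho.

    A cytoband is ``dup_effect`` when every method's effect is strictly
    positive, ``del_effect`` when all are strictly negative, otherwise
    ``not_correlated``.  Rho for a method pair is NaN when either effect
    vector is constant (undefined ranks).
    """
    effects = table.effects if isinstance(table, EffectTable) else table
    if len(effects) < min_cytobands:
        raise ValueError(f"need >= {min_cytobands} overlapping cytobands for correlation")
    arr = effects.to_numpy()
    labels = np.where(
        (arr > 0).all(axis=1), "dup_effect", np.where((arr < 0).all(axis=1), "del_effect", "not_correlated")
    )
    methods = list(effects.columns)
    rho = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for a, b in itertools.combinations(methods, 2):
        if effects[a].nunique() < 2 or effects[b].nunique() < 2:
            r = np.nan
        else:
            r = spearmanr(effects[a], effects[b]).statistic
        rho.loc[a, b] = rho.loc[b, a] = r
    return EffectTable(
        effects=effects,
        labels=pd.Series(labels, index=effects.index, name="label"),
        rho=rho,
    )


def knn_value_transfer(
    query: np.ndarray,
    reference: np.ndarray,
    values: np.ndarray,
    k: int = 50,
) -> np.ndarray:
    """Mean of the k nearest reference values for each query point.

    Distances are Euclidean in the shared embedding; ties are broken by
    reference index (stable sort), so results are deterministic.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    values = np.asarray(values, dtype=float)
    if query.shape[1] != reference.shape[1]:
        raise ValueError("query and reference must share one embedding dimensionality")
    if len(values) != len(reference):
        raise ValueError("one value per reference point required")
    if k < 1 or k > len(reference):
        raise ValueError("k must lie in 1..len(reference)")
    dist = cdist(query, reference)
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return values[nearest].mean(axis=1)
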