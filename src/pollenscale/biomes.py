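"""Biome typical assemblages, difference axes and score-based classification.

A biome's *typical assemblage* is the mean square-rooted assemblage of
recent (surface) pollen samples from sites whose modern land-cover
intersection classes belong to that biome.  Because widely dispersed taxa
(Pinus above all) contribute to nearly every biome, classification works on
*binary* comparisons: the difference axis ``a_ij = a_i - a_j`` between two
typical assemblages cancels shared dominants and isolates discriminating
taxa.  Projecting a fossil record's sqrt-proportion samples onto an axis
(uncentred dot product, so the sign at zero is meaningful) yields a score
series ``u_ij(t)``; its mean over the 8–2 ka BP window, ``u_bar``, is
positive for records closer to biome i and negative for biome j.

The iterative chain of the analysis — forest/open-land, then
needleleaf/broadleaf within forests, then boreal/temperate-coniferous
within needleleaf, then boreal evergreen/deciduous within the strongest
boreal quantiles — is driven by the filter rules implemented here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, InsufficientDataError
from .ordination import ScoreSeries
from .records import ANALYSIS_WINDOW, PollenRecord, to_proportions

logger = logging.getLogger(__name__)

#: Window defining "recent" surface samples, years BP (closed).
RECENT_WINDOW = (-60.0, 500.0)

#: Threshold for reporting taxa on an axis (|value| > 0.05).
AXIS_DISPLAY_THRESHOLD = 0.05


@dataclass
class TypicalAssemblage:
    biome_id: str
    weights: pd.Series              # mean sqrt-proportion per taxon, >= 0
    n_source_records: int
    class_selection: list[str]


@dataclass
class DifferenceAxis:
    axis_id: str                    # "i,j"; positive side = biome i
    values: pd.Series               # a_i - a_j on the taxon union

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    def display_taxa(self, threshold: float = AXIS_DISPLAY_THRESHOLD) -> pd.Series:
        """Taxa with |value| above the reporting threshold, ascending."""
        v = self.values[self.values.abs() > threshold]
        return v.sort_values()


@dataclass
class BiomeScore:
    site_id: str
    axis_id: str
    u_bar: float
    n_samples_in_window: int


def recent_assemblages(
    records: list[PollenRecord],
    window: tuple[float, float] = RECENT_WINDOW,
    transform_order: str = "mean_then_sqrt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record mean sqrt assemblage of samples in the recent window.

    ``transform_order`` controls whether proportions are averaged within a
    record before square-rooting (``mean_then_sqrt``, default) or
    square-rooted per sample first (``sqrt_then_mean``); the two differ
    slightly for records with heterogeneous recent samples.

    Returns ``(assemblages, meta)``: a sites x union-taxa DataFrame
    (zero-filled) and a per-site metadata frame with lat, lon, region and
    any class labels.  Records without recent samples are excluded.
    """
    if transform_order not in ("mean_then_sqrt", "sqrt_then_mean"):
        raise ValueError(f"unknown transform_order {transform_order!r}")
    rows, meta_rows = {}, []
    for rec in records:
        sub = rec.subset_window(window)
        if sub is None:
            continue
        props = to_proportions(sub).values
        if transform_order == "mean_then_sqrt":
            vec = np.sqrt(props.mean(axis=0))
        else:
            vec = np.sqrt(props).mean(axis=0)
        rows[rec.site_id] = pd.Series(vec, index=rec.taxa)
        meta_rows.append(
            {"site_id": rec.site_id, "lat": rec.lat, "lon": rec.lon,
             "region": rec.region, **rec.class_labels}
        )
    if not rows:
        return pd.DataFrame(), pd.DataFrame()
    assemblages = pd.DataFrame(rows).T.fillna(0.0).sort_index()
    meta = pd.DataFrame(meta_rows).set_index("site_id").sort_index()
    return assemblages, meta


def typical_assemblage(
    assemblages: pd.DataFrame,
    labels: pd.Series,
    biome_id: str,
    class_selection: list[str],
    group_weights: dict[str, float] | None = None,
) -> TypicalAssemblage:
    """Mean sqrt assemblage over the records of the selected classes.

    With ``group_weights`` (e.g. ``{"BorEvr": 0.5, "BorDec": 0.5}``) the
    mean is taken per class first and the class means combined with the
    stated weights regardless of group sizes — used to stop an
    over-represented sub-type (4x more boreal evergreen than deciduous
    surface records) from dominating the typical assemblage.
    """
    labels = labels.reindex(assemblages.index)
    sel = labels.isin(class_selection)
    if not sel.any():
        raise EmptySelectionError(
            f"no surface records in classes {class_selection} for biome {biome_id!r}"
        )
    if group_weights is None:
        weights = assemblages.loc[sel].mean(axis=0)
        n = int(sel.sum())
    else:
        parts, total_w = [], 0.0
        for cls, wgt in group_weights.items():
            grp = assemblages.loc[labels == cls]
            if grp.empty:
                raise EmptySelectionError(
                    f"group {cls!r} of biome {biome_id!r} matched no records"
                )
            parts.append(wgt * grp.mean(axis=0))
            total_w += wgt
        weights = sum(parts) / total_w
        n = int(labels.isin(list(group_weights)).sum())
    return TypicalAssemblage(
        biome_id=biome_id,
        weights=weights,
        n_source_records=n,
        class_selection=list(class_selection),
    )


def difference_axis(a_i: TypicalAssemblage, a_j: TypicalAssemblage) -> DifferenceAxis:
    """a_ij = a_i - a_j on the union taxon list (zero fill); positive = biome i."""
    union = a_i.weights.index.union(a_j.weights.index)
    vi = a_i.weights.reindex(union, fill_value=0.0)
    vj = a_j.weights.reindex(union, fill_value=0.0)
    return DifferenceAxis(axis_id=f"{a_i.biome_id},{a_j.biome_id}", values=vi - vj)


def project_scores(record: PollenRecord, axis: DifferenceAxis) -> ScoreSeries:
    """Project a fossil record onto a difference axis.

    Per sample the score is the uncentred dot product of the sample's
    sqrt-proportion row with the axis values, aligned on the taxon union
    with zero fill (equivalently, summed over shared taxa).  No centring is
    applied: the sign of the score at zero carries the biome identity.
    """
    shared = [t for t in record.taxa if t in axis.values.index]
    if not shared:
        raise EmptySelectionError(
            f"record {record.site_id} shares no taxa with axis {axis.axis_id}"
        )
    props = to_proportions(record)
    sqrt_rows = np.sqrt(props.values)
    axis_vec = axis.values.reindex(record.taxa, fill_value=0.0).to_numpy()
    return ScoreSeries(
        times=record.times.copy(),
        values=sqrt_rows @ axis_vec,
        source=axis.axis_id,
    )


def mean_score(
    score_series: ScoreSeries,
    window: tuple[float, float] = ANALYSIS_WINDOW,
    site_id: str = "",
) -> BiomeScore:
    """Mean score over the closed analysis window; NaN-flagged when empty."""
    lo, hi = sorted(window)
    mask = (score_series.times >= lo) & (score_series.times <= hi)
    if not mask.any():
        return BiomeScore(site_id=site_id, axis_id=score_series.source,
                          u_bar=float("nan"), n_samples_in_window=0)
    return BiomeScore(
        site_id=site_id,
        axis_id=score_series.source,
        u_bar=float(score_series.values[mask].mean()),
        n_samples_in_window=int(mask.sum()),
    )


def quantile_groups(scores: pd.Series, k: int = 5) -> pd.Series:
    """Equal-count rank bins 1..k (1 = lowest scores); sizes differ by <= 1.

    Ties are broken by stable input order.
    """
    n = scores.size
    if n < k:
        raise InsufficientDataError(f"need >= {k} sites for {k} quantile groups")
    order = np.argsort(scores.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(np.arange(n), k), start=1):
        labels[order[chunk]] = g
    return pd.Series(labels, index=scores.index, name="quantile_group")


def binary_filter(
    biome_scores: pd.Series,
    rule,
    regions: pd.Series | None = None,
) -> list[str]:
    """Select site ids according to a classification rule.

    Rules:

    * ``"positive"`` — sites with u_bar strictly > 0 (u_bar == 0 falls to
      the j side, logged);
    * ``("upper_q", fraction)`` — the top ``fraction`` of sites by u_bar
      (rank-based, floor of fraction*n sites);
    * ``("region", label)`` — sites whose region equals ``label``
      (requires ``regions``, a site-indexed Series).
    """
    s = biome_scores.dropna()
    if rule == "positive":
        if (s == 0).any():
            logger.info("binary_filter: %d sites with u_bar == 0 fall to the j side",
                        int((s == 0).sum()))
        return list(s.index[s > 0])
    if isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "upper_q":
        frac = float(rule[1])
        if not 0 < frac <= 1:
            raise ValueError("upper_q fraction must lie in (0, 1]")
        n_sel = int(np.floor(frac * s.size + 1e-9))
        order = np.argsort(s.to_numpy(), kind="stable")
        return list(s.index[order[::-1][:n_sel]])
    if isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "region":
        if regions is None:
            raise ValueError("region rule requires a site->region Series")
        sel = regions.reindex(s.index) == rule[1]
        return list(s.index[sel.fillna(False)])
    raise ValueError(f"unknown rule {rule!r}")
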