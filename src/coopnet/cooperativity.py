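"""Cooperativity rankings and region-level selectivity scores.

The *cooperativity* (node strength) of a contact node is the sum of the
strengths of all edges incident to it, in- and out-edges alike: a node
whose presence co-varies with many other contacts accumulates a large node
strength.  Nodes are ranked, the top quartile flagged, and the flagged set
aggregated over structural regions (TM helices / intracellular loops on the
receptor; N-terminus, core segments, alpha5-core and alpha5-tip on the
G protein).  A per-region *selectivity score* — the mean strength of
top-quartile nodes whose G-protein residue is not conserved across
subtypes — is compared against experimental coupling changes (dlogEC50 of
chimeric G proteins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContactNodeId, InsufficientDataError, UsageError
from .bn import BayesianNetwork


def node_strengths(net: BayesianNetwork) -> dict[ContactNodeId, float]:
    """Sum of incident edge strengths per node (isolated nodes score 0)."""
    out = {n: 0.0 for n in net.nodes}
    for (u, v), s in net.edge_strengths.items():
        out[u] += s
        out[v] += s
    return out


def rank_top_quartile(
    strengths: Mapping[ContactNodeId, float], q: float = 0.25
) -> pd.DataFrame:
    """Rank nodes by strength and flag the top ceil(q * N).

    Returns a DataFrame indexed by canonical node text with columns
    ``node``, ``node_strength``, ``rank`` (1 = strongest) and
    ``top_quartile``.  Ties break by label so the flagged set is
    deterministic; ceil keeps at least one node flagged for any N >= 1.
    """
    if not 0.0 < q <= 1.0:
        raise UsageError("quartile fraction q must be in (0, 1]")
    if not strengths:
        raise UsageError("rank_top_quartile needs at least one node")
    rows = sorted(
        strengths.items(), key=lambda kv: (-kv[1], kv[0].canonical_text)
    )
    n_flag = math.ceil(q * len(rows))
    df = pd.DataFrame(
        {
            "node": [n for n, _ in rows],
            "node_strength": [s for _, s in rows],
            "rank": np.arange(1, len(rows) + 1),
            "top_quartile": [i < n_flag for i in range(len(rows))],
        },
        index=pd.Index([n.canonical_text for n, _ in rows], name="canonical_text"),
    )
    return df


def annotate_table(
    table: pd.DataFrame,
    regions: Mapping[str, str] | None = None,
    polarities: Mapping[ContactNodeId, str] | None = None,
) -> pd.DataFrame:
    """Attach receptor_region / gprotein_region / polarity columns."""
    df = table.copy()
    if regions is not None:
        df["receptor_region"] = [
            _region_of(n.receptor_label.generic_id, regions) for n in df["node"]
        ]
        df["gprotein_region"] = [
            _region_of(n.gprotein_label.generic_id, regions) for n in df["node"]
        ]
    if polarities is not None:
        df["polarity"] = [
            polarities.get(n, polarities.get(n.canonical_text, "unknown"))
            if isinstance(polarities, dict) else "unknown"
            for n in df["node"]
        ]
    return df


def _region_of(generic_id: str, regions: Mapping[str, str]) -> str:
    try:
        return regions[generic_id]
    except KeyError:
        raise LookupError(
            f"generic_id {generic_id!r} has no region assignment"
        ) from None


@dataclass
class RegionAggregate:
    """Counts and fractions of cooperative nodes per region pair.

    ``fraction`` normalizes each G-protein region's row over the region's
    total *cooperative* (top-quartile) interactions, so the polar and
    non-polar heatmaps of one complex share a denominator and each row sums
    to 1 when no polarity filter is applied.  ``fraction_of_region_total``
    instead divides by all interactions the region makes, cooperative or
    not.
    """

    counts: pd.DataFrame
    fraction: pd.DataFrame
    fraction_of_region_total: pd.DataFrame
    n_flagged: int = 0
    polarity_filter: str | None = None


def aggregate_by_region(
    table: pd.DataFrame,
    regions: Mapping[str, str],
    polarity: str | None = None,
) -> RegionAggregate:
    """Cross-tabulate top-quartile nodes by (receptor region, G-protein region).

    ``polarity`` restricts the counted nodes to ``"polar"`` or
    ``"nonpolar"`` (requires a polarity column; see :func:`annotate_table`).
    Every node must be mappable; unmapped generic ids raise, listing the
    offenders.
    """
    nodes = list(table["node"])
    missing = sorted(
        {
            gid
            for n in nodes
            for gid in (n.receptor_label.generic_id, n.gprotein_label.generic_id)
            if gid not in regions
        }
    )
    if missing:
        raise LookupError(f"generic ids without region assignment: {missing}")
    if polarity is not None and "polarity" not in table.columns:
        raise UsageError("polarity filtering requires an annotated table")

    df = annotate_table(table, regions=regions)
    flagged = df[df["top_quartile"]]
    sel = flagged if polarity is None else flagged[flagged["polarity"] == polarity]

    rec_regions = sorted({regions[n.receptor_label.generic_id] for n in nodes})
    gp_regions = sorted({regions[n.gprotein_label.generic_id] for n in nodes})
    counts = pd.DataFrame(0, index=rec_regions, columns=gp_regions, dtype=int)
    for _, row in sel.iterrows():
        counts.loc[row["receptor_region"], row["gprotein_region"]] += 1

    flagged_per_gp = flagged["gprotein_region"].value_counts()
    total_per_gp = df["gprotein_region"].value_counts()
    frac = counts.astype(float)
    frac_total = counts.astype(float)
    for gp in gp_regions:
        nf = float(flagged_per_gp.get(gp, 0))
        nt = float(total_per_gp.get(gp, 0))
        frac[gp] = counts[gp] / nf if nf else 0.0
        frac_total[gp] = counts[gp] / nt if nt else 0.0
    return RegionAggregate(
        counts=counts,
        fraction=frac,
        fraction_of_region_total=frac_total,
        n_flagged=int(len(sel)),
        polarity_filter=polarity,
    )


@dataclass
class SelectivityScoreTable:
    """Per-G-protein-region cooperativity scores.

    ``scores[region]`` is the mean node strength over top-quartile nodes
    whose G-protein residue is unconserved; regions with no qualifying node
    get NaN with ``n_contributing`` 0 (reported, never dropped).
    """

    scores: dict[str, float] = field(default_factory=dict)
    n_contributing: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        regions = list(self.scores)
        return pd.DataFrame(
            {
                "region": regions,
                "cooperativity_score": [self.scores[r] for r in regions],
                "n_contributing_residues": [self.n_contributing[r] for r in regions],
            }
        )


def region_selectivity_scores(
    table: pd.DataFrame,
    regions: Mapping[str, str],
    conserved_flags: Mapping[str, bool],
) -> SelectivityScoreTable:
    """Mean strength of unconserved top-quartile nodes per G-protein region."""
    gp_ids = {n.gprotein_label.generic_id for n in table["node"]}
    missing_flags = sorted(g for g in gp_ids if g not in conserved_flags)
    if missing_flags:
        raise LookupError(f"conservation flag missing for: {missing_flags}")
    missing_regions = sorted(g for g in gp_ids if g not in regions)
    if missing_regions:
        raise LookupError(f"region missing for: {missing_regions}")

    gp_regions = sorted({regions[g] for g in gp_ids})
    buckets: dict[str, list[float]] = {r: [] for r in gp_regions}
    for _, row in table.iterrows():
        node: ContactNodeId = row["node"]
        gid = node.gprotein_label.generic_id
        if row["top_quartile"] and not conserved_flags[gid]:
            buckets[regions[gid]].append(float(row["node_strength"]))
    out = SelectivityScoreTable()
    for r in gp_regions:
        vals = buckets[r]
        out.scores[r] = float(np.mean(vals)) if vals else float("nan")
        out.n_contributing[r] = len(vals)
    return out


def correlate_with_coupling(
    scores: SelectivityScoreTable,
    measured: Mapping[str, float],
) -> dict:
    """Pearson and Spearman correlation of region scores vs dlogEC50.

    Regions with NaN scores (no qualifying residues) are excluded and
    reported.  Requires >= 3 paired regions; constant inputs are an error
    (the correlation is undefined).
    """
    paired, excluded = [], []
    for region, val in scores.scores.items():
        if region not in measured:
            continue
        if math.isnan(val):
            excluded.append(region)
            continue
        paired.append((region, val, float(measured[region])))
    if len(paired) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired regions, have {len(paired)} (excluded null: {excluded})"
        )
    x = np.array([p[1] for p in paired])
    y = np.array([p[2] for p in paired])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for constant input")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "pairs": [
            {"region": r, "cooperativity_score": s, "dlogec50": m}
            for r, s, m in paired
        ],
        "excluded_null_regions": excluded,
    }
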