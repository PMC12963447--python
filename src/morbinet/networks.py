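"""Directed multimorbidity networks from temporally ordered diagnoses.

For two conditions A and B in a cohort of N patients, the co-occurrence risk
ratio is observed over expected under independence,

    RR_AB = N_AB * N / (N_A * N_B),

and for three conditions the analogue is

    RR_ABC = N_ABC * N^2 / (N_A * N_B * N_C).

A directed pair A->B counts patients whose first onset of A strictly
precedes their first onset of B (same-day onsets contribute to co-occurrence
but to neither direction). Pairs are screened with a one-sided exact
hypergeometric (Fisher) test for positive association and kept only when
more than ``min_n`` patients carry both conditions and the p-value clears a
Bonferroni threshold alpha/m over the m evaluated pairs. Each retained pair
is labelled by where its onset sequences sit relative to the patients'
complexity transitions (pre / post / mixed).

Two network views are built: a general-population network (the most frequent
directed pairs, then the strongest remaining risk ratios touching those
diseases) and disease-centred subnetworks (most prevalent co-occurring
conditions around a central disease, then the directed pairs with the
highest triplet risk ratios with respect to it).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .simulate import age_band_label

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "DiseaseNetwork",
    "chronic_onsets",
    "count_pairs",
    "rr_pair",
    "rr_triplet",
    "pair_pvalue",
    "compute_pair_stats",
    "apply_filters",
    "classify_timing",
    "count_triplet",
    "build_general_network",
    "build_disease_centred",
    "pair_frequency_table",
    "triad_frequency_table",
    "onset_summary",
]


@dataclass(frozen=True)
class FilterConfig:
    """Count and significance filters for pair retention."""

    alpha: float = 0.05
    min_n: int = 50  # strict: pairs need more than min_n co-affected patients


@dataclass
class DiseaseNetwork:
    """Directed disease network: prevalence-sized nodes, tiered edges."""

    nodes: pd.DataFrame  # group_id, prevalence
    edges: pd.DataFrame  # source, target, n_directed, rr, timing, width, tier
    meta: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(**{k: v for k, v in self.meta.items() if np.isscalar(v)})
        for r in self.nodes.itertuples():
            g.add_node(r.group_id, prevalence=float(r.prevalence))
        for r in self.edges.itertuples():
            g.add_edge(
                r.source,
                r.target,
                n_directed=int(r.n_directed),
                rr=float(r.rr),
                timing=str(r.timing),
                width=float(r.width),
                tier=str(r.tier),
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_json_dict(self) -> dict:
        return {
            "meta": {k: v for k, v in self.meta.items()},
            "nodes": self.nodes.to_dict(orient="records"),
            "edges": self.edges.to_dict(orient="records"),
        }


def chronic_onsets(
    mapped_events: pd.DataFrame,
    include_classes: tuple[str, ...] = ("chronic", "neoplastic"),
) -> pd.DataFrame:
    """First onset per patient and long-term diagnostic group.

    The networks describe accumulating chronic disease, so acute and
    pregnancy-related groups are excluded by default; onsets recorded before
    baseline are kept (the full longitudinal record counts).
    """
    ev = mapped_events.loc[mapped_events["chronicity"].isin(include_classes)]
    onsets = (
        ev.groupby(["patient_id", "group_id"], sort=True)["onset_date"]
        .min()
        .reset_index()
    )
    onsets["onset_date"] = pd.to_datetime(onsets["onset_date"])
    return onsets


def _presence(onsets: pd.DataFrame) -> pd.DataFrame:
    """patient x group matrix of onset dates (NaT where never diagnosed)."""
    return onsets.pivot(index="patient_id", columns="group_id", values="onset_date")


def count_pairs(onsets: pd.DataFrame, n_total: int) -> pd.DataFrame:
    """Co-occurrence and directed counts for every pair with n_ab >= 1.

    One row per unordered pair (a < b lexicographically) with columns n_a,
    n_b, n_ab, n_dir_ab (a strictly first), n_dir_ba, n_total. A patient
    contributes at most once to n_ab and, unless the onsets tie, to exactly
    one directed count.
    """
    dup = onsets.duplicated(["patient_id", "group_id"])
    if dup.any():
        raise ValueError("duplicate chronic onset per patient-group")
    wide = _presence(onsets)
    groups = sorted(wide.columns)
    counts = {g: int(wide[g].notna().sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        da, db = wide[a], wide[b]
        both = da.notna() & db.notna()
        n_ab = int(both.sum())
        if n_ab == 0:
            continue
        n_dir_ab = int((both & (da < db)).sum())
        n_dir_ba = int((both & (db < da)).sum())
        rows.append(
            {
                "a": a,
                "b": b,
                "n_a": counts[a],
                "n_b": counts[b],
                "n_ab": n_ab,
                "n_dir_ab": n_dir_ab,
                "n_dir_ba": n_dir_ba,
                "n_total": int(n_total),
            }
        )
    return pd.DataFrame(
        rows, columns=["a", "b", "n_a", "n_b", "n_ab", "n_dir_ab", "n_dir_ba", "n_total"]
    )


def rr_pair(n_ab, n_a, n_b, n_total):
    """Co-occurrence risk ratio: observed / expected = n_ab * N / (n_a * n_b)."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a <= 0) or np.any(n_b <= 0) or n_total <= 0:
        raise ValueError("risk ratio undefined for zero margins")
    return np.asarray(n_ab, dtype=float) * float(n_total) / (n_a * n_b)


def rr_triplet(n_abc, n_a, n_b, n_c, n_total):
    """Triplet risk ratio: n_abc * N^2 / (n_a * n_b * n_c)."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    if np.any(n_a <= 0) or np.any(n_b <= 0) or np.any(n_c <= 0) or n_total <= 0:
        raise ValueError("risk ratio undefined for zero margins")
    return np.asarray(n_abc, dtype=float) * float(n_total) ** 2 / (n_a * n_b * n_c)


def pair_pvalue(n_ab, n_a, n_b, n_total):
    """One-sided exact tail P(X >= n_ab) under independence at fixed margins.

    X is hypergeometric: draw n_b patients from n_total of which n_a carry
    condition A. Exact at small counts and standard for co-occurrence
    enrichment screens.
    """
    n_ab = np.asarray(n_ab)
    return hypergeom.sf(n_ab - 1, int(n_total), np.asarray(n_a), np.asarray(n_b))


def compute_pair_stats(onsets: pd.DataFrame, n_total: int) -> pd.DataFrame:
    """count_pairs plus rr and p columns for every pair with n_ab >= 1."""
    stats = count_pairs(onsets, n_total)
    if not len(stats):
        stats["rr"] = pd.Series(dtype=float)
        stats["p"] = pd.Series(dtype=float)
        return stats
    stats["rr"] = rr_pair(stats["n_ab"], stats["n_a"], stats["n_b"], n_total)
    stats["p"] = pair_pvalue(stats["n_ab"], stats["n_a"], stats["n_b"], n_total)
    return stats


def apply_filters(
    stats: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, dict]:
    """Retain pairs with n_ab strictly above min_n and p below alpha/m.

    m is the number of evaluated pairs (every pair with at least one
    co-affected patient); the Bonferroni threshold and m are returned as
    metadata.
    """
    m = int(len(stats))
    threshold = config.alpha / m if m else float("nan")
    retained = stats.loc[(stats["n_ab"] > config.min_n) & (stats["p"] < threshold)].copy()
    meta = {"m": m, "alpha": config.alpha, "threshold": threshold, "min_n": config.min_n}
    return retained, meta


def count_triplet(wide: pd.DataFrame, a: str, b: str, c: str) -> int:
    """Number of patients diagnosed with all of a, b and c."""
    return int((wide[a].notna() & wide[b].notna() & wide[c].notna()).sum())


def classify_timing(
    onsets: pd.DataFrame,
    transitions: pd.DataFrame,
    a: str,
    b: str,
    theta: float = 2 / 3,
    never_transition: str = "pre",
) -> tuple[str | None, dict]:
    """Timing of the directed sequence a -> b relative to complexity transitions.

    Considers patients whose first onset of ``a`` strictly precedes that of
    ``b``. Per patient: if the patient never transitions, the sequence
    accumulated below the threshold and counts as ``never_transition``
    (default "pre"); if both onsets precede the transition date the label is
    pre; if the first onset is on/after it, post; otherwise spanning. The
    pair label is pre (post) when its fraction reaches ``theta``, else
    mixed. Returns (label, fractions); label None when no patient supports
    the direction.
    """
    wide = _presence(onsets)
    tdates = transitions.set_index("patient_id")["transition_date"]
    da = wide[a].reindex(wide.index)
    db = wide[b].reindex(wide.index)
    support = da.notna() & db.notna() & (da < db)
    n = int(support.sum())
    if n == 0:
        logger.info("no supporting patients for direction %s->%s", a, b)
        return None, {"pre": 0.0, "post": 0.0, "spanning": 0.0, "n": 0}
    t = tdates.reindex(wide.index)
    da_s, db_s, t_s = da[support], db[support], t[support]
    no_transition = t_s.isna()
    pre = no_transition if never_transition == "pre" else pd.Series(False, index=t_s.index)
    pre = pre | (~t_s.isna() & (db_s < t_s))
    post = ~t_s.isna() & (da_s >= t_s)
    spanning = ~pre & ~post
    if never_transition not in ("pre", "drop"):
        raise ValueError("never_transition must be 'pre' or 'drop'")
    if never_transition == "drop":
        keep = ~no_transition
        pre, post, spanning = pre[keep], post[keep], spanning[keep]
        n = int(keep.sum())
        if n == 0:
            return None, {"pre": 0.0, "post": 0.0, "spanning": 0.0, "n": 0}
    fractions = {
        "pre": float(pre.sum()) / n,
        "post": float(post.sum()) / n,
        "spanning": float(spanning.sum()) / n,
        "n": n,
    }
    if fractions["pre"] >= theta:
        label = "pre"
    elif fractions["post"] >= theta:
        label = "post"
    else:
        label = "mixed"
    return label, fractions


def _directed_frame(stats: pd.DataFrame) -> pd.DataFrame:
    """Expand unordered pair stats into directed rows (each direction
    treated independently; zero-count directions dropped)."""
    fwd = stats.rename(columns={"a": "source", "b": "target", "n_dir_ab": "n_directed"})[
        ["source", "target", "n_directed", "n_ab", "rr", "p"]
    ]
    rev = stats.rename(columns={"b": "source", "a": "target", "n_dir_ba": "n_directed"})[
        ["source", "target", "n_directed", "n_ab", "rr", "p"]
    ]
    directed = pd.concat([fwd, rev], ignore_index=True)
    return directed.loc[directed["n_directed"] > 0].reset_index(drop=True)


def _scale_widths(counts: np.ndarray) -> np.ndarray:
    """Min-max normalise directed counts to display widths in [1, 10]."""
    counts = counts.astype(float)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return np.full_like(counts, 10.0)
    return 1.0 + 9.0 * (counts - lo) / (hi - lo)


def _attach_timing(
    edges: pd.DataFrame, onsets: pd.DataFrame, transitions: pd.DataFrame | None, theta: float
) -> pd.Series:
    labels = []
    for r in edges.itertuples():
        if transitions is None:
            labels.append("mixed")
            continue
        label, _ = classify_timing(onsets, transitions, r.source, r.target, theta=theta)
        labels.append(label if label is not None else "mixed")
    return pd.Series(labels, index=edges.index, dtype=object)


def prevalence_by_group(onsets: pd.DataFrame, n_total: int) -> pd.Series:
    counts = onsets.groupby("group_id")["patient_id"].nunique()
    return counts / n_total


def build_general_network(
    stats: pd.DataFrame,
    onsets: pd.DataFrame,
    n_total: int,
    transitions: pd.DataFrame | None = None,
    k_primary: int = 30,
    k_secondary: int = 60,
    theta: float = 2 / 3,
) -> DiseaseNetwork:
    """General-population network with a two-tier selection hierarchy.

    Tier 1: the ``k_primary`` most frequent directed pairs across the cohort
    (each direction independent), ranked by directed count, then risk ratio,
    then lexicographic ids. Tier 2: among the remaining directed pairs that
    involve at least one tier-1 disease, the ``k_secondary`` strongest by
    co-occurrence risk ratio (then count, then ids). ``stats`` should
    already be filtered for counts and significance. Node sizes carry
    end-of-study prevalence; edge widths are the directed counts min-max
    normalised to [1, 10].
    """
    directed = _directed_frame(stats)
    directed = directed.sort_values(
        ["n_directed", "rr", "source", "target"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    if len(directed) < k_primary:
        logger.warning(
            "only %d eligible directed pairs for %d primary slots", len(directed), k_primary
        )
    tier1 = directed.head(k_primary).copy()
    primary_diseases = set(tier1["source"]) | set(tier1["target"])
    rest = directed.iloc[len(tier1):]
    touching = rest.loc[
        rest["source"].isin(primary_diseases) | rest["target"].isin(primary_diseases)
    ]
    tier2 = touching.sort_values(
        ["rr", "n_directed", "source", "target"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).head(k_secondary).copy()
    tier1["tier"] = "primary"
    tier2["tier"] = "secondary"
    edges = pd.concat([tier1, tier2], ignore_index=True)
    if len(edges):
        edges["width"] = _scale_widths(edges["n_directed"].values)
        edges["timing"] = _attach_timing(edges, onsets, transitions, theta)
    else:
        edges["width"] = pd.Series(dtype=float)
        edges["timing"] = pd.Series(dtype=object)
    prev = prevalence_by_group(onsets, n_total)
    node_ids = sorted(set(edges["source"]) | set(edges["target"]))
    nodes = pd.DataFrame(
        {"group_id": node_ids, "prevalence": [float(prev.get(g, 0.0)) for g in node_ids]}
    )
    return DiseaseNetwork(
        nodes=nodes,
        edges=edges[
            ["source", "target", "n_directed", "n_ab", "rr", "p", "timing", "width", "tier"]
        ],
        meta={"kind": "general", "k_primary": k_primary, "k_secondary": k_secondary},
    )


def build_disease_centred(
    central: str,
    stats: pd.DataFrame,
    onsets: pd.DataFrame,
    n_total: int,
    transitions: pd.DataFrame | None = None,
    k_secondary: int = 10,
    k_tertiary: int = 20,
    theta: float = 2 / 3,
) -> DiseaseNetwork:
    """Subnetwork centred on one condition.

    Secondary conditions are the ``k_secondary`` most prevalent co-occurring
    conditions with the central one (by co-occurrence count among filtered
    pairs). Tertiary edges are the ``k_tertiary`` directed pairs between a
    secondary condition and any other non-central condition with the highest
    triplet risk ratios computed jointly with the central condition.
    """
    wide = _presence(onsets)
    if central not in wide.columns:
        raise ValueError(f"central condition {central!r} absent from cohort")
    margins = {g: int(wide[g].notna().sum()) for g in wide.columns}

    with_central = stats.loc[(stats["a"] == central) | (stats["b"] == central)].copy()
    with_central["other"] = np.where(
        with_central["a"] == central, with_central["b"], with_central["a"]
    )
    secondary = (
        with_central.sort_values(
            ["n_ab", "rr", "other"], ascending=[False, False, True], kind="mergesort"
        )
        .head(k_secondary)
    )
    secondary_ids = list(secondary["other"])

    # central <-> secondary edges, oriented by the dominant directed count
    sec_edges = []
    for r in secondary.itertuples():
        if r.a == central:
            fwd, rev = r.n_dir_ab, r.n_dir_ba
        else:
            fwd, rev = r.n_dir_ba, r.n_dir_ab
        src, dst, n_dir = (central, r.other, fwd) if fwd >= rev else (r.other, central, rev)
        sec_edges.append(
            {
                "source": src,
                "target": dst,
                "n_directed": int(n_dir),
                "n_ab": int(r.n_ab),
                "rr": float(r.rr),
                "p": float(r.p),
                "tier": "secondary",
                "triplet_rr": np.nan,
            }
        )

    # tertiary: directed pairs (secondary, other non-central), ranked by
    # triplet RR with the central condition
    directed = _directed_frame(stats)
    cand = directed.loc[
        (directed["source"].isin(secondary_ids) | directed["target"].isin(secondary_ids))
        & (directed["source"] != central)
        & (directed["target"] != central)
    ].copy()
    trr = []
    for r in cand.itertuples():
        n_abc = count_triplet(wide, central, r.source, r.target)
        trr.append(
            float(
                rr_triplet(
                    n_abc, margins[central], margins[r.source], margins[r.target], n_total
                )
            )
        )
    cand["triplet_rr"] = trr
    tertiary = cand.sort_values(
        ["triplet_rr", "n_directed", "source", "target"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).head(k_tertiary)
    tertiary = tertiary.assign(tier="tertiary")[
        ["source", "target", "n_directed", "n_ab", "rr", "p", "tier", "triplet_rr"]
    ]
    edges = pd.concat([pd.DataFrame(sec_edges), tertiary], ignore_index=True)
    if len(edges):
        edges["width"] = _scale_widths(edges["n_directed"].values)
        edges["timing"] = _attach_timing(edges, onsets, transitions, theta)
    else:
        edges["width"] = pd.Series(dtype=float)
        edges["timing"] = pd.Series(dtype=object)
    prev = prevalence_by_group(onsets, n_total)
    node_ids = sorted({central} | set(edges["source"]) | set(edges["target"]))
    nodes = pd.DataFrame(
        {"group_id": node_ids, "prevalence": [float(prev.get(g, 0.0)) for g in node_ids]}
    )
    return DiseaseNetwork(
        nodes=nodes,
        edges=edges[
            [
                "source",
                "target",
                "n_directed",
                "n_ab",
                "rr",
                "p",
                "triplet_rr",
                "timing",
                "width",
                "tier",
            ]
        ],
        meta={"kind": "disease_centred", "central": central, "k_secondary": k_secondary, "k_tertiary": k_tertiary},
    )


def pair_frequency_table(stats: pd.DataFrame, n_total: int, top_k: int = 20) -> pd.DataFrame:
    """Most frequent co-occurring pairs with cohort percentages."""
    out = stats.sort_values(
        ["n_ab", "a", "b"], ascending=[False, True, True], kind="mergesort"
    ).head(top_k)[["a", "b", "n_ab"]].copy()
    out["pct"] = out["n_ab"] / n_total * 100.0
    return out.reset_index(drop=True)


def triad_frequency_table(onsets: pd.DataFrame, n_total: int, top_k: int = 20) -> pd.DataFrame:
    """Most frequent condition triads with cohort percentages."""
    wide = _presence(onsets)
    groups = sorted(wide.columns)
    present = wide.notna().to_numpy()
    rows = []
    for i, j, k in itertools.combinations(range(len(groups)), 3):
        n_abc = int((present[:, i] & present[:, j] & present[:, k]).sum())
        if n_abc:
            rows.append({"a": groups[i], "b": groups[j], "c": groups[k], "n_abc": n_abc})
    table = pd.DataFrame(rows, columns=["a", "b", "c", "n_abc"])
    table = table.sort_values(
        ["n_abc", "a", "b", "c"], ascending=[False, True, True, True], kind="mergesort"
    ).head(top_k)
    table["pct"] = table["n_abc"] / n_total * 100.0
    return table.reset_index(drop=True)


def onset_summary(
    onsets: pd.DataFrame, patients: pd.DataFrame, codemap
) -> pd.DataFrame:
    """Chronic-condition onsets by organ system x age band x sex.

    Counts every first onset among patients with at least one chronic
    condition; age is the patient's age at that onset.
    """
    merged = onsets.merge(
        patients[["patient_id", "sex", "birth_date"]], on="patient_id", how="left"
    )
    age = (
        pd.to_datetime(merged["onset_date"]) - pd.to_datetime(merged["birth_date"])
    ).dt.days / 365.25
    merged["age_band"] = age_band_label(age.clip(lower=18.0).values)
    merged["organ_system"] = merged["group_id"].map(
        {g: info.organ_system for g, info in codemap.groups.items()}
    )
    table = (
        merged.groupby(["organ_system", "age_band", "sex"], sort=True)
        .size()
        .rename("n_onsets")
        .reset_index()
    )
    return table
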