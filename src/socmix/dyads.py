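"""Dyadic dataset construction.

A dyad is an unordered pair of samples from two distinct birds captured in the
same field period (one breeding season of one year). Responses are similarity
scores: the negated Aitchison distance per stratum and the negated absolute
alpha-diversity difference, so that larger values always mean "more similar".
Covariates are absolute differences (age, time of day, time in season),
equality indicators (sex), the shared period's season, pedigree relatedness,
and a shared-nest-at-hatch flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "build_dyads",
    "status_pair_category",
    "nest_sharing_lump",
    "shared_nest_at_hatch",
    "filter_within_group",
    "STATUS_PAIR_LEVELS",
    "NEST_SHARING_LEVELS",
]

logger = logging.getLogger(__name__)

#: within-group social-status pair categories, reference level first
STATUS_PAIR_LEVELS = ("DomDom", "DomHelp", "DomSub", "HelpSub", "SubSub")
NEST_SHARING_LEVELS = ("nest_sharing", "non_nest_sharing")

_DOM = {"DomM", "DomF"}


def status_pair_category(status_a: str, status_b: str, *,
                         group_a: str | None = None,
                         group_b: str | None = None) -> str:
    """Unordered social-status pair category of a within-group dyad.

    {DomM,DomF} -> DomDom; {Dom*,Helper} -> DomHelp; {Dom*,Sub} -> DomSub;
    {Helper,Sub} -> HelpSub; {Sub,Sub} -> SubSub. Helper-Helper pairs fall
    outside the five categories and are returned as 'HelpHelp' so callers can
    flag and exclude them.
    """
    if group_a is not None and group_b is not None and group_a != group_b:
        raise ValueError("status pair categories are defined within a group only")
    s = {status_a, status_b}
    if not s <= {"DomM", "DomF", "Helper", "Sub"}:
        raise ValueError(f"unknown statuses: {s}")
    n_dom = sum(1 for x in (status_a, status_b) if x in _DOM)
    if n_dom == 2:
        return "DomDom"
    if n_dom == 1:
        return "DomHelp" if "Helper" in s else "DomSub"
    if s == {"Helper"}:
        return "HelpHelp"
    if s == {"Sub"}:
        return "SubSub"
    return "HelpSub"


def nest_sharing_lump(category: str) -> str:
    """Lump status-pair categories by whether the pair cooperates at a nest.

    Dom-Dom and Dom-Help pairs interact directly at a shared nest; the
    remaining categories (involving a non-helping subordinate) do not.
    """
    if category in ("DomDom", "DomHelp"):
        return "nest_sharing"
    if category in ("DomSub", "HelpSub", "SubSub"):
        return "non_nest_sharing"
    raise ValueError(f"not a status-pair category: {category!r}")


def _parse_nest_set(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    return frozenset(x for x in str(value).split(";") if x)


def shared_nest_at_hatch(bird_a_row: pd.Series, bird_b_row: pd.Series) -> bool:
    """True iff one bird attended the other's natal nest (parent, helper or
    sibling — a shared natal nest counts because each bird's attendance set
    includes its own natal nest). Missing natal records give False."""
    natal_a = bird_a_row.get("natal_nest_id")
    natal_b = bird_b_row.get("natal_nest_id")
    pres_a = _parse_nest_set(bird_a_row.get("present_at_nest_ids"))
    pres_b = _parse_nest_set(bird_b_row.get("present_at_nest_ids"))
    if not isinstance(natal_a, str) or not isinstance(natal_b, str):
        logger.warning("missing natal nest record for %s/%s; shared_nest_at_hatch=False",
                       bird_a_row.get("bird_id"), bird_b_row.get("bird_id"))
        return False
    return (natal_a in pres_b) or (natal_b in pres_a)


def _shared_nest_matrix(meta: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    """Precompute the symmetric bird x bird shared-nest-at-hatch indicator."""
    birds = meta.drop_duplicates("bird_id").set_index("bird_id")
    ids = list(birds.index)
    idx = {b: i for i, b in enumerate(ids)}
    natal = [birds.loc[b, "natal_nest_id"] if "natal_nest_id" in birds.columns else None
             for b in ids]
    pres = [_parse_nest_set(birds.loc[b, "present_at_nest_ids"])
            if "present_at_nest_ids" in birds.columns else frozenset()
            for b in ids]
    n = len(ids)
    m = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if isinstance(natal[i], str) and isinstance(natal[j], str):
                v = (natal[i] in pres[j]) or (natal[j] in pres[i])
            else:
                v = False
            m[i, j] = m[j, i] = v
    return m, idx


def build_dyads(metadata: pd.DataFrame, distances: dict,
                alpha: pd.DataFrame, relatedness: pd.DataFrame) -> pd.DataFrame:
    """Enumerate within-period sample pairs from distinct birds and attach
    responses and differenced covariates.

    Parameters
    ----------
    metadata : per-sample table with the SampleMetadata columns.
    distances : mapping stratum name -> skbio DistanceMatrix covering all
        samples in ``metadata``; each yields a ``neg_distance_<name>`` response.
    alpha : per-sample richness/shannon table indexed by sample_id.
    relatedness : square bird x bird matrix; dyads whose relatedness is
        missing are dropped with a logged count.
    """
    if metadata["sample_id"].duplicated().any():
        dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dup[:5]}")

    meta = metadata.reset_index(drop=True)
    sn_matrix, bird_idx = _shared_nest_matrix(meta)

    dist_arrays = {}
    for name, dm in distances.items():
        order = [dm.index(s) for s in meta["sample_id"]]
        dist_arrays[name] = np.asarray(dm.data)[np.ix_(order, order)]
    alpha_al = alpha.loc[meta["sample_id"]]
    rich = alpha_al["richness"].to_numpy(dtype=float)
    shan = alpha_al["shannon"].to_numpy(dtype=float)

    rel = relatedness
    rel_ids = {b: i for i, b in enumerate(rel.index)}
    rel_vals = rel.to_numpy(dtype=float)

    bird = meta["bird_id"].to_numpy()
    group = meta["group_id"].to_numpy()
    status = meta["status"].to_numpy()
    sex = meta["sex"].to_numpy()
    age = meta["age_years"].to_numpy(dtype=float)
    day = meta["day_in_season"].to_numpy(dtype=float)
    tod = meta["minutes_after_sunrise"].to_numpy(dtype=float)
    year = meta["year"].to_numpy()
    season = meta["season"].to_numpy()
    sample = meta["sample_id"].to_numpy()

    frames = []
    n_missing_rel = 0
    for period in sorted(meta["period_id"].unique()):
        pos = np.flatnonzero((meta["period_id"] == period).to_numpy())
        if len(pos) < 2:
            continue
        ia, ib = np.triu_indices(len(pos), k=1)
        a, b = pos[ia], pos[ib]
        distinct = bird[a] != bird[b]
        a, b = a[distinct], b[distinct]
        if len(a) == 0:
            continue

        ra = np.array([rel_ids.get(x, -1) for x in bird[a]])
        rb = np.array([rel_ids.get(x, -1) for x in bird[b]])
        have = (ra >= 0) & (rb >= 0)
        relat = np.full(len(a), np.nan)
        relat[have] = rel_vals[ra[have], rb[have]]
        ok = np.isfinite(relat)
        n_missing_rel += int((~ok).sum())
        a, b, relat = a[ok], b[ok], relat[ok]
        if len(a) == 0:
            continue

        bi_a = np.array([bird_idx[x] for x in bird[a]])
        bi_b = np.array([bird_idx[x] for x in bird[b]])
        row = {
            "sample_a": sample[a], "sample_b": sample[b],
            "bird_a": bird[a], "bird_b": bird[b],
            "group_a": group[a], "group_b": group[b],
            "status_a": status[a], "status_b": status[b],
            "same_group": (group[a] == group[b]).astype(int),
            "age_diff": np.abs(age[a] - age[b]),
            "sex_diff": np.where(sex[a] == sex[b], "same", "different"),
            "season": season[a],
            "tod_diff": np.abs(tod[a] - tod[b]),
            "tis_diff": np.abs(day[a] - day[b]),
            "relatedness": relat,
            "shared_nest_at_hatch": sn_matrix[bi_a, bi_b].astype(int),
            "year": year[a],
            "period_id": period,
            "neg_richness_diff": -np.abs(rich[a] - rich[b]),
            "neg_shannon_diff": -np.abs(shan[a] - shan[b]),
        }
        for name, dmat in dist_arrays.items():
            row[f"neg_distance_{name}"] = -dmat[a, b]
        frames.append(pd.DataFrame(row))

    if n_missing_rel:
        logger.warning("dropped %d dyads with missing relatedness", n_missing_rel)
    if not frames:
        raise ValueError("no dyads could be formed (need >=2 samples from "
                         "distinct birds in some period)")
    return pd.concat(frames, ignore_index=True)


def filter_within_group(dyads: pd.DataFrame) -> pd.DataFrame:
    """Restrict to within-group dyads and attach status-pair categories.

    Helper-Helper pairs have no slot in the five-category scheme and are
    excluded with a logged count.
    """
    out = dyads.loc[dyads["same_group"] == 1].copy()
    if out.empty:
        raise ValueError("no within-group dyads")
    cats = [status_pair_category(sa, sb)
            for sa, sb in zip(out["status_a"], out["status_b"])]
    out["status_pair"] = cats
    hh = out["status_pair"] == "HelpHelp"
    if hh.any():
        logger.warning("excluding %d Helper-Helper within-group dyads", int(hh.sum()))
        out = out.loc[~hh].copy()
    if out.empty:
        raise ValueError("no within-group dyads after Helper-Helper exclusion")
    out["nest_sharing"] = [nest_sharing_lump(c) for c in out["status_pair"]]
    return out.reset_index(drop=True)
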