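"""Reanalysis of germ-free co-housing competition experiments.

Ex-germ-free (GF) mice are co-housed with a wildling (wild-microbiota) and
a laboratory donor; which strains establish in the GF gut measures relative
fitness in vivo. The pipeline rarefies the ASV count table, keeps
*diagnostic* ASVs — those within co-diversified taxa detected at day 0 in
exactly one of the two source groups — computes Dice dissimilarities among
diagnostic presence profiles, ordinates them, and tests (i) whether GF
communities end up closer to the wildling than to the laboratory source,
with permutation t-tests on per-mouse averages, and (ii) whether
wildling-derived ASVs outnumber laboratory-derived ASVs of the same genus
over the late phase of the experiment (days 7–17).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from skbio import DistanceMatrix

from .cophylo import PCoAEmbedding, pcoa
from .phylo import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "select_diagnostic",
    "dice_dissimilarity",
    "dice_matrix",
    "source_dissimilarities",
    "group_permutation_test",
    "trajectory_test",
    "pcoa_ordination",
]


def _check_meta(meta: pd.DataFrame) -> None:
    required = {"mouse_id", "group", "day"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    bad = set(meta["group"]) - {"wildling", "lab", "GF"}
    if bad:
        raise ValueError(f"unknown sample groups: {sorted(bad)}")


def rarefy(tbl: pd.DataFrame, depth: int, rng_seed=0) -> pd.DataFrame:
    """Subsample every sample (row) to exactly ``depth`` reads without
    replacement; samples below ``depth`` are dropped with a log message."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = as_rng(rng_seed)
    totals = tbl.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = sorted(set(tbl.index) - set(keep))
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:5])
    if len(keep) == 0:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    out = pd.DataFrame(0, index=keep, columns=tbl.columns, dtype=np.int64)
    for sample in keep:
        counts = tbl.loc[sample].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            out.loc[sample] = counts
        else:
            out.loc[sample] = rng.multivariate_hypergeometric(counts, depth)
    return out


def select_diagnostic(tbl: pd.DataFrame, meta: pd.DataFrame, taxonomy: pd.Series,
                      codiv_taxa) -> pd.Series:
    """Diagnostic ASVs: in a co-diversified taxon and detected at day 0 in
    exactly one source group.

    Returns ASV -> source label (``wildling_derived`` or ``lab_derived``).
    Detection means count > 0 in at least one day-0 sample of that group.
    """
    codiv_taxa = set(codiv_taxa)
    if not codiv_taxa:
        raise ValueError("empty set of co-diversified taxa")
    _check_meta(meta)
    day0 = meta[meta["day"] == 0]
    for grp in ("wildling", "lab"):
        if not (day0["group"] == grp).any():
            raise ValueError(f"no day-0 samples for group {grp!r}")
    out = {}
    for grp in ("wildling", "lab"):
        samples = day0.index[day0["group"] == grp]
        present = tbl.loc[tbl.index.intersection(samples)].sum(axis=0) > 0
        out[grp] = set(present.index[present])
    for asv in tbl.columns:
        if taxonomy.get(asv, "unclassified") not in codiv_taxa:
            out["wildling"].discard(asv)
            out["lab"].discard(asv)
    only_w = out["wildling"] - out["lab"]
    only_l = out["lab"] - out["wildling"]
    labels = {a: "wildling_derived" for a in only_w}
    labels.update({a: "lab_derived" for a in only_l})
    return pd.Series(labels, dtype=object).sort_index()


def dice_dissimilarity(profile_a, profile_b) -> float:
    """Dice dissimilarity 1 - 2|A∩B|/(|A|+|B|) on presence sets.

    Two empty profiles are defined as identical (0); this degenerate case
    is logged.
    """
    a, b = set(profile_a), set(profile_b)
    if not a and not b:
        logger.debug("dice: two empty profiles, returning 0")
        return 0.0
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def dice_matrix(presence: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Dice dissimilarities among samples of a binary table."""
    samples = list(presence.index)
    sets = {s: set(presence.columns[presence.loc[s] > 0]) for s in samples}
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = dice_dissimilarity(sets[samples[i]], sets[samples[j]])
    return DistanceMatrix(d, ids=samples)


def source_dissimilarities(tbl: pd.DataFrame, meta: pd.DataFrame,
                           diagnostic: pd.Series) -> pd.DataFrame:
    """Dice dissimilarity of every GF sample to every day-0 source sample.

    Profiles are presence/absence over the diagnostic ASVs. Returns a long
    table with columns gf_sample, gf_mouse, day, source_group, value.
    """
    _check_meta(meta)
    asvs = [a for a in diagnostic.index if a in tbl.columns]
    presence = (tbl[asvs] > 0).astype(int)
    gf = meta[(meta["group"] == "GF") & (meta["day"] >= 1)]
    day0 = meta[(meta["day"] == 0) & (meta["group"].isin(["wildling", "lab"]))]
    sets = {s: set(presence.columns[presence.loc[s] > 0]) for s in presence.index}
    rows = []
    for g in gf.index:
        for s in day0.index:
            rows.append({
                "gf_sample": g,
                "gf_mouse": gf.loc[g, "mouse_id"],
                "day": int(gf.loc[g, "day"]),
                "source_group": day0.loc[s, "group"],
                "value": dice_dissimilarity(sets[g], sets[s]),
            })
    return pd.DataFrame(rows)


def group_permutation_test(values: pd.DataFrame, contrast, n_perm: int = 999,
                           rng_seed=0, value_col: str = "value",
                           unit_col: str = "gf_mouse",
                           group_col: str = "source_group"):
    """Two-sided permutation t-test on per-mouse averaged values.

    Longitudinal values are first averaged within each (mouse, group) unit,
    so every mouse contributes one number per contrasted group; the group
    labels of these unit averages are then permuted. p = (1 + c)/(1 + B).

    Returns ``(t_obs, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g1, g2 = contrast
    rng = as_rng(rng_seed)
    sub = values[values[group_col].isin([g1, g2])]
    means = sub.groupby([unit_col, group_col], observed=True)[value_col].mean().reset_index()
    x = means.loc[means[group_col] == g1, value_col].to_numpy()
    y = means.loc[means[group_col] == g2, value_col].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 mouse-averaged values per group")
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def tstat(a, b):
        va = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        if va == 0:
            return 0.0
        return (a.mean() - b.mean()) / np.sqrt(va)

    t_obs = tstat(x, y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        t_p = tstat(pooled[perm[:n1]], pooled[perm[n1:]])
        if abs(t_p) >= abs(t_obs) - 1e-12:
            count += 1
    return float(t_obs), (1 + count) / (1 + n_perm)


def trajectory_test(tbl: pd.DataFrame, meta: pd.DataFrame, diagnostic: pd.Series,
                    taxonomy: pd.Series, genus: str, day_window=(7, 17)):
    """Late-phase advantage of wildling-derived over lab-derived ASVs of a genus.

    For every GF sample in the day window, the difference in relative
    abundance (wildling-derived minus lab-derived diagnostic ASVs of the
    genus) is computed; a one-sample two-sided t-test asks whether the mean
    difference departs from zero. Returns ``(mean_diff, p)``.
    """
    _check_meta(meta)
    asvs = [a for a in diagnostic.index
            if a in tbl.columns and taxonomy.get(a) == genus]
    if not asvs:
        raise ValueError(f"no diagnostic ASVs for genus {genus!r}")
    w_asvs = [a for a in asvs if diagnostic[a] == "wildling_derived"]
    l_asvs = [a for a in asvs if diagnostic[a] == "lab_derived"]
    lo, hi = day_window
    gf = meta[(meta["group"] == "GF") & meta["day"].between(lo, hi)]
    if len(gf) == 0:
        raise ValueError(f"no GF samples within days {lo}-{hi}")
    totals = tbl.loc[gf.index].sum(axis=1).replace(0, np.nan)
    w_ab = tbl.loc[gf.index, w_asvs].sum(axis=1) / totals if w_asvs else 0.0 * totals
    l_ab = tbl.loc[gf.index, l_asvs].sum(axis=1) / totals if l_asvs else 0.0 * totals
    diffs = (w_ab - l_ab).dropna().to_numpy()
    mean_diff = float(diffs.mean())
    if len(diffs) < 2 or np.std(diffs) == 0:
        return mean_diff, 1.0 if mean_diff == 0 else 0.0
    res = st.ttest_1samp(diffs, 0.0)
    return mean_diff, float(res.pvalue)


def pcoa_ordination(dissims: DistanceMatrix) -> PCoAEmbedding:
    """Principal coordinates of a Dice dissimilarity matrix (Cailliez)."""
    return pcoa(dissims, correction="cailliez")
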