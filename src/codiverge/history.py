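"""Retention/extinction accounting of ancestral clades and molecular clocks.

A significant, non-nested co-diversifying clade is called *ancestral to
murids* when it contains genomes from the focal host (Mus musculus
domesticus), from at least one other murid, and from at least one outgroup
to murids — i.e. the symbiosis predates the murid radiation. Over these
ancestral clades, presence/absence in wild versus laboratory house mice is
tabulated and compared by a Pearson chi-squared test (no continuity
correction). Clock regressions relate symbiont sequence divergence within
strongly co-diversifying clades to host divergence times.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st

from .phylo import TreeIndex

__all__ = [
    "CLADE_ROLES",
    "classify_ancestral",
    "build_retention_table",
    "retention_contingency",
    "ClockFit",
    "clock_regression",
    "read_roles",
    "read_divergence_times",
    "divergence_times_from_tree",
]

CLADE_ROLES = frozenset({"focal_mmd", "other_murid", "outgroup"})

#: host categories contributing to each retention flag
_CATEGORY_FLAGS = ("wild_mouse", "lab_mouse", "wildling", "rewilded", "ex_wild")


def read_roles(path) -> dict:
    """Read a roles TSV (host_species, clade_role) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df["clade_role"]) - CLADE_ROLES
    if bad:
        raise ValueError(f"unknown clade roles: {sorted(bad)}")
    return dict(zip(df["host_species"], df["clade_role"]))


def classify_ancestral(records, tree, meta, roles: dict, ti: TreeIndex = None):
    """Clade ids containing >=1 focal, >=1 other-murid, and >=1 outgroup tip."""
    ti = ti or TreeIndex(tree)
    host_of = meta["host_species"].to_dict()
    missing = {host_of[t] for t in meta.index} - set(roles)
    if missing:
        raise ValueError(f"host species without a clade role: {sorted(missing)}")
    out = []
    for rec in records:
        seen = {roles[host_of[t]] for t in ti.node_tips(rec.node_id)}
        if CLADE_ROLES <= seen:
            out.append(rec.node_id)
    return out


def build_retention_table(clade_ids, tree, meta, ti: TreeIndex = None) -> pd.DataFrame:
    """Per-clade presence flags for each house-mouse category.

    A clade is "present in" a category when at least one of its tips carries
    that host category; "lost from" a category means zero such tips.
    """
    ti = ti or TreeIndex(tree)
    cat_of = meta["host_category"].to_dict()
    rows = {}
    for cid in clade_ids:
        cats = {cat_of[t] for t in ti.node_tips(cid)}
        rows[cid] = {flag: flag in cats for flag in _CATEGORY_FLAGS}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(_CATEGORY_FLAGS))


def retention_contingency(tbl: pd.DataFrame):
    """Chi-squared test for differential loss of ancestral clades.

    Builds the 2x2 table of (absent, present) counts for wild versus
    laboratory house mice over the ancestral clades and applies Pearson's
    chi-squared with df=1 and *no* continuity correction.

    Returns ``(chi2, p, table)`` where ``table`` rows are (wild, lab) and
    columns (absent, present).
    """
    if len(tbl) == 0:
        raise ValueError("no ancestral clades to tabulate")
    table = np.array(
        [
            [int((~tbl["wild_mouse"]).sum()), int(tbl["wild_mouse"].sum())],
            [int((~tbl["lab_mouse"]).sum()), int(tbl["lab_mouse"].sum())],
        ]
    )
    res = st.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq == 0):
        raise ValueError("zero expected cell count; use an exact test")
    return float(res.statistic), float(res.pvalue), table


@dataclass(frozen=True)
class ClockFit:
    slope: float
    intercept: float
    ci95: tuple
    r2: float
    n_pairs: int


def read_divergence_times(path) -> dict:
    """Read a divergence-time TSV (species_a, species_b, mya) into a dict
    keyed by frozen species pair."""
    df = pd.read_csv(path, sep="\t")
    times = {}
    for a, b, t in df.itertuples(index=False):
        if t <= 0:
            raise ValueError(f"non-positive divergence time for ({a}, {b})")
        times[frozenset((a, b))] = float(t)
    return times


def divergence_times_from_tree(host_tree, scale: float = 1.0) -> dict:
    """Pairwise divergence times from an ultrametric host tree.

    Time of a pair = half its patristic distance (times ``scale``, e.g. to
    convert branch-length units to million years).
    """
    from .phylo import patristic_distances

    D = patristic_distances(host_tree)
    ids = list(D.ids)
    return {
        frozenset((a, b)): scale * D[a, b] / 2.0
        for a, b in combinations(ids, 2)
    }


def clock_regression(symb_D, times: dict, links) -> ClockFit:
    """OLS of pairwise symbiont divergence on host divergence time.

    Every cross-host-species pair of linked symbiont tips contributes one
    point (x = host divergence time, y = symbiont patristic distance). The
    95% confidence interval on the slope uses the t distribution with
    n - 2 degrees of freedom. Pairs are used without correction for their
    phylogenetic non-independence.
    """
    links = list(links)
    xs, ys = [], []
    for (s1, h1), (s2, h2) in combinations(links, 2):
        if h1 == h2:
            continue
        key = frozenset((h1, h2))
        if key not in times:
            raise KeyError(f"no divergence time for host pair {sorted(key)}")
        xs.append(times[key])
        ys.append(symb_D[s1, s2])
    if len(xs) < 3:
        raise ValueError("need at least 3 cross-host tip pairs")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("all pairs share one host divergence time (rank deficient)")
    fit = st.linregress(x, y)
    n = len(x)
    tcrit = st.t.ppf(0.975, n - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return ClockFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ci95=(float(ci[0]), float(ci[1])),
        r2=float(fit.rvalue**2),
        n_pairs=n,
    )
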