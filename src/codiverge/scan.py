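"""Phylogeny-wide scans for co-diversification.

The scan walks every internal node of the symbiont (MAG) phylogeny that
passes three filters — at least ``min_hosts`` host species, at least
``min_symbionts`` genomes, and a clade span below ``span_fraction`` of the
whole-tree span (restricting tests to the distal part of the phylogeny,
where clades postdate the radiation of the hosts) — and runs the Hommola
permutation test on each. Clades passing r > ``r_threshold`` and
p < ``p_threshold`` are called co-diversifying.

Because nested clades share tips, per-node p-values are not independent and
FDR corrections do not apply; instead :func:`null_label_scan` permutes the
host-species labels on the host tree and re-runs the whole scan to obtain a
null distribution for the *number* of significant clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .cophylo import (
    UndefinedStatisticError,
    hommola_test,
    paco_test,
    parafit_test,
)
from .phylo import Clade, TreeIndex, collapse_host_monophyletic, validate_tip_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "CladeTestRecord",
    "NullScanResult",
    "select_testable_nodes",
    "scan_tree",
    "dereplicated_scan",
    "null_label_scan",
    "sensitivity_scan",
    "resolve_nested",
    "records_to_frame",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan filters and thresholds; the defaults are the study settings."""

    min_hosts: int = 3
    min_symbionts: int = 7
    span_fraction: float = 0.25
    n_perm: int = 999
    r_threshold: float = 0.75
    p_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.span_fraction <= 1):
            raise ValueError("span_fraction must be in (0, 1]")
        if self.min_hosts < 2 or self.min_symbionts < 2 or self.n_perm < 1:
            raise ValueError("invalid scan configuration")


@dataclass(frozen=True)
class CladeTestRecord:
    node_id: str
    n_hosts: int
    n_symbionts: int
    r: float
    p: float
    significant: bool


@dataclass(frozen=True)
class NullScanResult:
    observed_count: int
    null_counts: list = field(default_factory=list)
    p_value: float = 1.0


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_id": r.node_id,
                "n_hosts": r.n_hosts,
                "n_symbionts": r.n_symbionts,
                "r": r.r,
                "p": r.p,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def _node_seed(master: int, k: int) -> np.random.Generator:
    # per-node streams: reproducible regardless of evaluation order
    return np.random.default_rng(np.random.SeedSequence(entropy=master, spawn_key=(k,)))


def _host_distances(host_tree: dendropy.Tree) -> DistanceMatrix:
    from .phylo import patristic_distances

    return patristic_distances(host_tree)


def select_testable_nodes(tree, meta, cfg: ScanConfig, ti: TreeIndex = None):
    """Internal nodes passing the host-count, size, and span filters, in preorder."""
    ti = ti or TreeIndex(tree)
    validate_tip_metadata(tree, meta)
    host_of = meta["host_species"].to_dict()
    total = ti.total_span()
    out = []
    for node_id in ti.nodes:  # insertion order = preorder
        tips = ti.node_tips(node_id)
        if len(tips) < cfg.min_symbionts:
            continue
        if len({host_of[t] for t in tips}) < cfg.min_hosts:
            continue
        span = ti.span(node_id)
        if total > 0 and span >= cfg.span_fraction * total:
            continue
        out.append(Clade(node_id=node_id, tips=frozenset(tips), span=span))
    return out


def scan_tree(tree, host_tree, meta, cfg: ScanConfig = None, *, host_D=None, ti=None):
    """Run the Hommola test on every testable node; one record per node.

    Nodes whose statistic is undefined (e.g. zero distance variance) are
    recorded with r = p = NaN and excluded from significance counts.
    """
    cfg = cfg or ScanConfig()
    ti = ti or TreeIndex(tree)
    host_D = host_D if host_D is not None else _host_distances(host_tree)
    host_of = meta["host_species"].to_dict()
    records = []
    for k, clade in enumerate(select_testable_nodes(tree, meta, cfg, ti)):
        tips = ti.node_tips(clade.node_id)
        links = [(t, host_of[t]) for t in tips]
        symb_D = _submatrix(ti, tips)
        try:
            res = hommola_test(
                host_D, symb_D, links, n_perm=cfg.n_perm, rng_seed=_node_seed(cfg.rng_seed, k)
            )
            sig = res.statistic > cfg.r_threshold and res.p_value < cfg.p_threshold
            records.append(
                CladeTestRecord(
                    clade.node_id, len({h for _, h in links}), len(tips),
                    res.statistic, res.p_value, sig,
                )
            )
        except (UndefinedStatisticError, KeyError) as exc:
            logger.warning("node %s skipped: %s", clade.node_id, exc)
            records.append(
                CladeTestRecord(
                    clade.node_id, len({h for _, h in links}), len(tips),
                    float("nan"), float("nan"), False,
                )
            )
    return records


def _submatrix(ti: TreeIndex, tips) -> DistanceMatrix:
    ix = np.asarray([ti.tip_index[t] for t in tips])
    return DistanceMatrix(ti.matrix[np.ix_(ix, ix)], ids=list(tips))


_TESTS = {"hommola": hommola_test, "paco": paco_test, "parafit": parafit_test}


def dereplicated_scan(tree, host_tree, meta, cfg: ScanConfig = None,
                      methods=("hommola", "paco", "parafit")) -> pd.DataFrame:
    """Collapsed scan: dereplicate each testable clade to one genome per
    same-host monophyletic group, then run the requested tests.

    Returns a table with one row per clade: per-method statistic and p, the
    number of tests significant at ``p_threshold``, and ``multi_support``
    (at least two tests significant). Clades that collapse below 3 links or
    ``min_hosts`` hosts are skipped with a logged reason.
    """
    cfg = cfg or ScanConfig()
    unknown = set(methods) - set(_TESTS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ti = TreeIndex(tree)
    host_D = _host_distances(host_tree)
    host_of = meta["host_species"].to_dict()
    rows = []
    for k, clade in enumerate(select_testable_nodes(tree, meta, cfg, ti)):
        rng = _node_seed(cfg.rng_seed, k)
        kept = collapse_host_monophyletic(tree, meta, clade, rng)
        links = [(t, host_of[t]) for t in kept]
        if len(kept) < 3 or len({h for _, h in links}) < cfg.min_hosts:
            logger.info("node %s skipped after collapsing (%d links)",
                        clade.node_id, len(kept))
            continue
        symb_D = _submatrix(ti, kept)
        row = {"node_id": clade.node_id, "n_links": len(kept)}
        n_sig = 0
        for method in methods:
            try:
                res = _TESTS[method](host_D, symb_D, links,
                                     n_perm=cfg.n_perm, rng_seed=rng)
                row[f"{method}_stat"] = res.statistic
                row[f"{method}_p"] = res.p_value
                n_sig += res.p_value < cfg.p_threshold
            except UndefinedStatisticError as exc:
                logger.warning("node %s %s skipped: %s", clade.node_id, method, exc)
                row[f"{method}_stat"] = float("nan")
                row[f"{method}_p"] = float("nan")
        row["n_significant_tests"] = n_sig
        row["multi_support"] = n_sig >= 2
        rows.append(row)
    return pd.DataFrame(rows)


def null_label_scan(tree, host_tree, meta, cfg: ScanConfig = None,
                    n_label_perms: int = 100) -> NullScanResult:
    """Host-label permutation null for the number of significant clades.

    Species names are shuffled across the host-tree tips (symbiont links
    follow the species name, so only the host distance structure changes)
    and the full scan is repeated per permutation.
    """
    cfg = cfg or ScanConfig()
    if n_label_perms < 1:
        raise ValueError("n_label_perms must be >= 1")
    ti = TreeIndex(tree)
    host_D = _host_distances(host_tree)
    observed = sum(
        r.significant for r in scan_tree(tree, host_tree, meta, cfg, host_D=host_D, ti=ti)
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(0xA11,))
    )
    ids = list(host_D.ids)
    null_counts = []
    for _ in range(n_label_perms):
        perm = rng.permutation(len(ids))
        permuted = DistanceMatrix(host_D.data, ids=[ids[i] for i in perm])
        n_sig = sum(
            r.significant
            for r in scan_tree(tree, host_tree, meta, cfg, host_D=permuted, ti=ti)
        )
        null_counts.append(n_sig)
    p = (1 + sum(c >= observed for c in null_counts)) / (1 + n_label_perms)
    return NullScanResult(observed, null_counts, p)


def sensitivity_scan(tree, host_tree, meta, cfg: ScanConfig = None) -> pd.DataFrame:
    """Leave-one-host-out robustness of the scan.

    For each host species, all its genomes are pruned, the scan is re-run,
    and the number of significant clades plus the fraction of originally
    significant clades still recovered (matched by surviving tip set) is
    reported.
    """
    cfg = cfg or ScanConfig()
    hosts = sorted(meta["host_species"].unique())
    if len(hosts) < 4:
        raise ValueError("need at least 4 host species for a leave-one-out scan")
    ti = TreeIndex(tree)
    base = scan_tree(tree, host_tree, meta, cfg, ti=ti)
    base_sig = {frozenset(ti.node_tips(r.node_id)) for r in base if r.significant}
    rows = []
    for host in hosts:
        drop = set(meta.index[meta["host_species"] == host])
        keep_taxa = [t for t in ti.tips if t not in drop]
        pruned = tree.extract_tree_with_taxa_labels(keep_taxa)
        pruned_meta = meta.loc[keep_taxa]
        sub = scan_tree(pruned, host_tree, pruned_meta, cfg)
        pti = TreeIndex(pruned)
        sub_sig = {frozenset(pti.node_tips(r.node_id)) for r in sub if r.significant}
        retained = (
            sum((tips - drop) in sub_sig for tips in base_sig) / len(base_sig)
            if base_sig
            else float("nan")
        )
        rows.append(
            {"host_species": host, "n_significant": len(sub_sig),
             "retained_fraction": retained}
        )
    return pd.DataFrame(rows)


def resolve_nested(records, tree, ti: TreeIndex = None):
    """Keep only significant clades with no significant ancestor.

    The result is an antichain under the descendant relation: the most
    inclusive significant clades, matching the notion of phylogenetically
    independent (non-nested) clades.
    """
    ti = ti or TreeIndex(tree)
    sig = [r for r in records if r.significant]
    sig_ids = {r.node_id for r in sig}
    out = []
    for rec in sig:
        node = ti.nodes[rec.node_id].parent_node
        nested = False
        while node is not None:
            if node.label in sig_ids:
                nested = True
                break
            node = node.parent_node
        if not nested:
            out.append(rec)
    return out
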