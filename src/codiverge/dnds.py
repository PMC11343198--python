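"""Branch dN/dS estimation and laboratory-versus-wild selection contrasts.

dN/dS (omega) is estimated by the Nei–Gojobori (1986) counting approach:
synonymous and nonsynonymous *sites* are counted per codon (mutations to
stop codons excluded), observed differences between two codons are resolved
by averaging over all stop-free minimal mutational pathways, and the raw
proportions are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4) ln(1 - (4/3) p).

Per-branch estimates on a gene tree compare each tip sequence to the
ancestral sequence of its parent node, reconstructed by Fitch parsimony per
nucleotide column with a deterministic tie-break. Downstream statistics —
quadrant classification of per-gene group means, the binomial asymmetry
test, paired genome-wide drift tests on log dN/dS, Benjamini–Hochberg
correction, and a Brownian-simulation phylogenetic ANOVA — operate on these
per-branch values.

Genome-wide elevation of dN/dS in one host environment, across genes, is
the signature of relaxed purifying selection under reduced effective
population size, i.e. elevated genetic drift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as st
from Bio.Data import CodonTable
from statsmodels.stats.multitest import multipletests

from .phylo import as_rng

__all__ = [
    "GeneFamily",
    "BranchDnDs",
    "GeneDnDsSummary",
    "ng86_sites",
    "ng86_pairwise",
    "branch_dnds",
    "gene_summary",
    "quadrant_classify",
    "binomial_asymmetry",
    "paired_drift_test",
    "bh_adjust",
    "clade_drift_tests",
    "phyl_anova",
    "fitch_ancestral_sequences",
]

BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def translate(codon: str) -> str:
    """Amino acid for a sense codon; '*' for stops."""
    return "*" if codon in STOP_CODONS else _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class GeneFamily:
    """An in-frame codon alignment with its gene tree and tip groups."""

    gene_id: str
    alignment: dict  # tip -> nucleotide sequence, length divisible by 3
    gene_tree: object  # dendropy.Tree
    tip_group: dict  # tip -> {"lab", "wild", "other"}

    def __post_init__(self):
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment sequences must share a length divisible by 3")
        groups = set(self.tip_group.values())
        if not {"lab", "wild"} <= groups:
            raise ValueError("need at least one lab and one wild tip")


@dataclass(frozen=True)
class BranchDnDs:
    branch_id: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    dn: float
    ds: float
    dnds: float  # NaN when undefined (dN or dS zero/saturated)
    group: str = "other"


@dataclass(frozen=True)
class GeneDnDsSummary:
    gene_id: str
    mean_lab_dnds: float
    mean_wild_dnds: float
    n_lab_branches: int
    n_wild_branches: int


# ---------------------------------------------------------------------------
# NG86 site and pathway tables


@lru_cache(maxsize=1)
def _site_table():
    """Per-codon (n_sites, s_sites). Changes to stop codons are excluded
    from both numerator and denominator, so a codon with stop neighbors
    contributes slightly less than 3 total sites."""
    table = np.zeros((64, 2))
    for ci, codon in enumerate(CODONS):
        if codon in STOP_CODONS:
            table[ci] = np.nan
            continue
        aa = translate(codon)
        n = s = 0.0
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue
                if translate(mut) == aa:
                    s += 1.0 / 3.0
                else:
                    n += 1.0 / 3.0
        table[ci] = (n, s)
    return table


def _path_counts(a: str, b: str, allow_stops: bool):
    diffs = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur = a
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != b and not allow_stops:
                ok = False
                break
            if translate(cur) == translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            results.append((nd, sd))
    return results


@lru_cache(maxsize=1)
def _pair_table():
    """Per-codon-pair (Nd, Sd) averaged over stop-free minimal pathways.

    If every pathway between two sense codons passes through a stop (rare),
    all pathways are used with stop steps counted as nonsynonymous.
    """
    nd_t = np.zeros((64, 64))
    sd_t = np.zeros((64, 64))
    for ci, a in enumerate(CODONS):
        if a in STOP_CODONS:
            nd_t[ci] = sd_t[ci] = np.nan
            continue
        for cj, b in enumerate(CODONS):
            if b in STOP_CODONS:
                nd_t[ci, cj] = sd_t[ci, cj] = np.nan
                continue
            if a == b:
                continue
            paths = _path_counts(a, b, allow_stops=False)
            if not paths:
                paths = _path_counts(a, b, allow_stops=True)
            nds, sds = zip(*paths)
            nd_t[ci, cj] = float(np.mean(nds))
            sd_t[ci, cj] = float(np.mean(sds))
    return nd_t, sd_t


def ng86_sites(codon: str):
    """(n_sites, s_sites) for one unambiguous sense codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r}")
    n, s = _site_table()[_CODON_INDEX[codon]]
    return float(n), float(s)


def _encode_codons(seq: str) -> np.ndarray:
    """Codon index array; -1 for codons with gaps/ambiguity or stops."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k : 3 * k + 3]
        out[k] = (
            _CODON_INDEX[codon]
            if all(b in BASES for b in codon) and codon not in STOP_CODONS
            else -1
        )
    return out


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); NaN at saturation."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - p * 4.0 / 3.0)


def ng86_pairwise(seq_a: str, seq_b: str, branch_id: str = "pair",
                  group: str = "other") -> BranchDnDs:
    """Nei–Gojobori dN/dS between two equal-length in-frame sequences.

    Site totals are averaged across the two sequences; codons containing
    gaps, ambiguity, or stops in either sequence are skipped.
    """
    ca = _encode_codons(seq_a)
    cb = _encode_codons(seq_b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in length")
    valid = (ca >= 0) & (cb >= 0)
    if not valid.any():
        raise ValueError("no comparable codons")
    sites = _site_table()
    nd_t, sd_t = _pair_table()
    n_sites = float((sites[ca[valid], 0] + sites[cb[valid], 0]).sum() / 2.0)
    s_sites = float((sites[ca[valid], 1] + sites[cb[valid], 1]).sum() / 2.0)
    nd = float(nd_t[ca[valid], cb[valid]].sum())
    sd = float(sd_t[ca[valid], cb[valid]].sum())
    dn = jukes_cantor(nd / n_sites) if n_sites > 0 else float("nan")
    ds = jukes_cantor(sd / s_sites) if s_sites > 0 else float("nan")
    dnds = dn / ds if (dn and ds and dn > 0 and ds > 0 and np.isfinite(dn) and np.isfinite(ds)) else float("nan")
    return BranchDnDs(branch_id, n_sites, s_sites, nd, sd,
                      float(dn), float(ds), float(dnds), group)


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral sequences

_NT_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BIT_NT = {1: "A", 2: "C", 4: "G", 8: "T"}


def _lowest_bit(mask: np.ndarray) -> np.ndarray:
    return mask & (-mask)


def fitch_ancestral_sequences(tree, alignment: dict) -> dict:
    """Fitch-parsimony nucleotide states for every internal node.

    Gaps and ambiguous bases are treated as fully ambiguous ({A,C,G,T}) so
    they never force a change. Ties are broken deterministically: a node
    takes its parent's state when compatible with its own state set,
    otherwise the alphabetically first base in the set (the root, having no
    parent, always takes the latter).

    Returns node -> sequence string for internal nodes.
    """
    length = len(next(iter(alignment.values())))
    down = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            seq = alignment[node.taxon.label].upper()
            mask = np.array([_NT_BITS.get(b, 15) for b in seq], dtype=np.int16)
            down[node] = mask
        else:
            children = [down[c] for c in node.child_nodes()]
            inter = children[0].copy()
            union = children[0].copy()
            for m in children[1:]:
                inter &= m
                union |= m
            down[node] = np.where(inter > 0, inter, union)
    states = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        mask = down[node]
        # fallback state: prefer the first child's downpass state when the
        # parent state is unavailable (ties resolve toward the descendants)
        child_mask = mask & down[node.child_nodes()[0]]
        fallback = np.where(child_mask > 0, _lowest_bit(child_mask), _lowest_bit(mask))
        if node.parent_node is None:
            chosen = fallback
        else:
            parent = states[node.parent_node]
            keep = (mask & parent) > 0
            chosen = np.where(keep, parent, fallback)
        states[node] = chosen
        out[node] = "".join(_BIT_NT[int(b)] for b in chosen)
    if length and out:
        assert all(len(s) == length for s in out.values())
    return out


def branch_dnds(fam: GeneFamily):
    """Terminal-branch dN/dS for a gene family.

    Each tip is compared to the Fitch-reconstructed sequence of its parent
    node. Gene trees with fewer than 3 tips fall back to the direct pairwise
    comparison between the two tips (each tip then carries that estimate).
    """
    tree = fam.gene_tree
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if set(tips) != set(fam.alignment):
        raise ValueError("alignment tips do not match gene tree tips")
    if len(tips) < 2:
        raise ValueError("gene tree must have at least 2 tips")
    if len(tips) < 3:
        a, b = tips
        pair = ng86_pairwise(fam.alignment[a], fam.alignment[b])
        return [
            BranchDnDs(t, pair.n_sites, pair.s_sites, pair.nd, pair.sd,
                       pair.dn, pair.ds, pair.dnds, fam.tip_group.get(t, "other"))
            for t in tips
        ]
    anc = fitch_ancestral_sequences(tree, fam.alignment)
    out = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        parent_seq = anc[leaf.parent_node]
        est = ng86_pairwise(parent_seq, fam.alignment[label], branch_id=label,
                            group=fam.tip_group.get(label, "other"))
        out.append(est)
    return out


def gene_summary(fam: GeneFamily, branches=None) -> GeneDnDsSummary:
    """Unweighted group means of defined branch dN/dS values.

    Branches with undefined dN/dS (zero or saturated dN or dS) do not enter
    the mean; a group with no defined branch yields NaN.
    """
    branches = branches if branches is not None else branch_dnds(fam)
    vals = {"lab": [], "wild": []}
    counts = {"lab": 0, "wild": 0}
    for b in branches:
        if b.group in vals:
            counts[b.group] += 1
            if np.isfinite(b.dnds):
                vals[b.group].append(b.dnds)
    mean = {g: (float(np.mean(v)) if v else float("nan")) for g, v in vals.items()}
    return GeneDnDsSummary(fam.gene_id, mean["lab"], mean["wild"],
                           counts["lab"], counts["wild"])


# ---------------------------------------------------------------------------
# Gene-level statistics


def quadrant_classify(summaries) -> dict:
    """Count genes by the (lab mean vs 1, wild mean vs 1) quadrant.

    Genes with a mean exactly 1 belong to neither positive class; genes
    with an undefined mean are ignored.
    """
    counts = {"lab_pos_wild_pur": 0, "wild_pos_lab_pur": 0,
              "both_pos": 0, "both_pur": 0}
    for s in summaries:
        lab, wild = s.mean_lab_dnds, s.mean_wild_dnds
        if not (np.isfinite(lab) and np.isfinite(wild)):
            continue
        if lab > 1 and wild < 1:
            counts["lab_pos_wild_pur"] += 1
        elif wild > 1 and lab < 1:
            counts["wild_pos_lab_pur"] += 1
        elif lab > 1 and wild > 1:
            counts["both_pos"] += 1
        elif lab < 1 and wild < 1:
            counts["both_pur"] += 1
    return counts


def binomial_asymmetry(k: int, n: int) -> float:
    """Exact two-sided binomial test of k successes in n trials against 1/2."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(st.binomtest(k, n, 0.5).pvalue)


def _paired_diffs(summaries, subset: str) -> np.ndarray:
    diffs = []
    for s in summaries:
        lab, wild = s.mean_lab_dnds, s.mean_wild_dnds
        if not (np.isfinite(lab) and np.isfinite(wild) and lab > 0 and wild > 0):
            continue
        if subset == "purifying_only" and not (lab < 1 and wild < 1):
            continue
        diffs.append(np.log(lab) - np.log(wild))
    return np.asarray(diffs)


def paired_drift_test(summaries, subset: str = "all"):
    """Paired t-test on per-gene log(lab mean dN/dS) - log(wild mean dN/dS).

    ``subset="purifying_only"`` keeps only genes with both means below 1
    (purifying selection in both environments), isolating the drift signal
    from genes under positive selection.
    """
    if subset not in ("all", "purifying_only"):
        raise ValueError(f"unknown subset {subset!r}")
    diffs = _paired_diffs(summaries, subset)
    if len(diffs) < 2:
        raise ValueError("need at least 2 genes with defined means")
    if np.all(diffs == 0):
        return 0.0, 1.0
    if np.std(diffs) == 0:
        raise ValueError("zero variance of paired differences")
    res = st.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def clade_drift_tests(summaries_by_clade: dict, subset: str = "all") -> pd.DataFrame:
    """Per-clade paired drift tests with BH correction across clades."""
    rows = []
    for clade_id, summaries in summaries_by_clade.items():
        t, p = paired_drift_test(summaries, subset)
        rows.append({"clade_id": clade_id, "t": t, "p": p,
                     "n_genes": len(_paired_diffs(summaries, subset))})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


def _vcv_matrix(tree, order):
    """Brownian covariance: C[i, j] = root distance of the MRCA of tips i, j."""
    idx = {lbl: i for i, lbl in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))
    depth = {}
    below = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            below[node] = [i]
            C[i, i] = depth[node]
        else:
            groups = [below[c] for c in node.child_nodes()]
            for gi, gj in itertools.combinations(groups, 2):
                C[np.ix_(gi, gj)] = depth[node]
                C[np.ix_(gj, gi)] = depth[node]
            below[node] = [i for g in groups for i in g]
    return C


def _anova_f(x: np.ndarray, group_codes: np.ndarray, n_groups: int) -> float:
    n = len(x)
    grand = x.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        xg = x[group_codes == g]
        ss_between += len(xg) * (xg.mean() - grand) ** 2
        ss_within += ((xg - xg.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def phyl_anova(tree, trait: dict, groups: dict, n_sim: int = 1000, rng_seed=0):
    """Phylogenetic ANOVA with a Brownian-motion simulation null.

    The observed statistic is the ordinary one-way ANOVA F of the trait
    across groups; its null distribution comes from ``n_sim`` simulations
    of Brownian motion on the tree with rate set to the phylogenetically
    (GLS) estimated trait variance. p = (1 + #{F_sim >= F_obs}) / (1 + n_sim).
    """
    rng = as_rng(rng_seed)
    order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    x = np.asarray([trait[t] for t in order], dtype=float)
    labels = [groups[t] for t in order]
    uniq = sorted(set(labels))
    codes = np.asarray([uniq.index(g) for g in labels])
    if len(uniq) < 2 or min(np.bincount(codes)) < 2:
        raise ValueError("need >= 2 groups with >= 2 tips each")
    if np.ptp(x) == 0:
        return 0.0, 1.0
    f_obs = _anova_f(x, codes, len(uniq))
    C = _vcv_matrix(tree, order)
    Cinv = np.linalg.inv(C + 1e-12 * np.eye(len(order)))
    ones = np.ones(len(order))
    mu = float(ones @ Cinv @ x / (ones @ Cinv @ ones))
    resid = x - mu
    sig2 = float(resid @ Cinv @ resid / len(order))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(order)))
    count = 0
    for _ in range(n_sim):
        y = mu + np.sqrt(sig2) * (L @ rng.standard_normal(len(order)))
        if _anova_f(y, codes, len(uniq)) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (1 + n_sim)
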