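"""Synthetic-data generators for every stage of the pipeline.

The generators emulate the statistical structure the analyses assume —
hosts diversifying under a Yule process, symbiont clades that either track
the host tree (with rate noise, host switches, and within-host genome
replicates) or are independent of it, codon alignments evolving with
branch-class-specific omega, and a germ-free co-housing experiment whose
colonization dynamics favor one source community — together with the
ground-truth labels needed for recovery and calibration tests.

Every generator takes an explicit seed (or Generator) and is fully
deterministic given it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .dnds import BASES, GeneFamily, SENSE_CODONS, STOP_CODONS, translate
from .phylo import as_rng

__all__ = [
    "SimConfig",
    "ScanDataset",
    "simulate_host_tree",
    "simulate_codiv_clade",
    "simulate_random_clade",
    "simulate_scan_dataset",
    "simulate_codon_alignment",
    "simulate_gene_families",
    "simulate_competition_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults encode the study conditions."""

    n_hosts: int = 10
    host_tree_model: str = "yule"
    n_codiv_clades: int = 5
    n_random_clades: int = 20
    host_switch_prob: float = 0.0
    rate_noise_sd: float = 0.1
    mags_per_host: int = 2
    gene_length_codons: int = 300
    omega_lab: float = 0.6
    omega_wild: float = 0.3
    kappa: float = 2.0
    advantage: float = 0.5
    depth: int = 40000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_hosts < 3 or self.mags_per_host < 1 or self.depth < 1:
            raise ValueError("invalid counts in SimConfig")
        if not 0 <= self.host_switch_prob <= 1:
            raise ValueError("host_switch_prob must be in [0, 1]")
        if self.omega_lab <= 0 or self.omega_wild <= 0 or self.kappa <= 0:
            raise ValueError("omega and kappa must be positive")
        if self.host_tree_model not in ("yule", "fixed"):
            raise ValueError(f"unknown host tree model {self.host_tree_model!r}")


@dataclass
class ScanDataset:
    tree: dendropy.Tree
    host_tree: dendropy.Tree
    meta: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trees


def _yule_tree(n_tips: int, labels, rng) -> dendropy.Tree:
    """Pure-birth (unit-rate) ultrametric tree with n_tips tips."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    # active lineages carry their birth time; split at exponential waits
    t = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / len(active))
    for node, born in active:
        node.edge.length = t - born
    leaves = list(tree.leaf_node_iter())
    shuffled = [labels[i] for i in rng.permutation(len(leaves))]
    for leaf, lbl in zip(leaves, shuffled):
        leaf.taxon = taxa.new_taxon(lbl)
    return tree


def simulate_host_tree(cfg: SimConfig, rng_seed=None) -> dendropy.Tree:
    """Ultrametric host-species tree labeled host_1..host_n.

    ``host_tree_model="fixed"`` yields a deterministic ladder (caterpillar)
    tree with unit internode lengths instead of a random Yule draw.
    """
    labels = [f"host_{i + 1}" for i in range(cfg.n_hosts)]
    if cfg.host_tree_model == "fixed":
        return _ladder_tree(labels)
    rng = as_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    return _yule_tree(cfg.n_hosts, labels, rng)


def _ladder_tree(labels) -> dendropy.Tree:
    n = len(labels)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    node = tree.seed_node
    for k in range(n - 1):
        depth_left = float(n - 1 - k)
        tip = node.new_child()
        tip.taxon = taxa.new_taxon(labels[k])
        tip.edge.length = depth_left
        if k < n - 2:
            inner = node.new_child()
            inner.edge.length = 1.0
            node = inner
        else:
            tip2 = node.new_child()
            tip2.taxon = taxa.new_taxon(labels[n - 1])
            tip2.edge.length = depth_left
    return tree


def _host_subtree(host_tree, min_hosts: int, rng):
    """A random internal node's host set with >= min_hosts species (or all)."""
    candidates = []
    for node in host_tree.preorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if len(tips) >= min_hosts:
            candidates.append(tips)
    return candidates[int(rng.integers(len(candidates)))]


def simulate_codiv_clade(host_tree, cfg: SimConfig, rng_seed=0, clade_id="c0",
                         hosts=None, min_hosts: int = 5, rate_scale: float = 1.0):
    """A symbiont clade tracking the host tree.

    The symbiont tree copies a host subtree's topology, multiplies each
    branch length by exp(N(0, rate_noise_sd^2)) (times ``rate_scale``),
    re-associates each symbiont lineage to a uniformly chosen other host
    with probability ``host_switch_prob`` (a host switch), then sprouts
    ``mags_per_host`` genome tips per lineage on short within-host branches.

    Returns ``(tree, links)`` with links as (tip_label, host_species).
    """
    rng = as_rng(rng_seed)
    if hosts is None:
        hosts = _host_subtree(host_tree, min(min_hosts, cfg.n_hosts), rng)
    if len(hosts) < 3:
        raise ValueError("need a host subtree of >= 3 species")
    sub = host_tree.extract_tree_with_taxa_labels(hosts)
    sub.is_rooted = True
    for edge in sub.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * rate_scale * float(
                np.exp(rng.normal(0.0, cfg.rate_noise_sd))
            )
    # host switching: re-associate tips, labels stay with the lineage
    assoc = {}
    for leaf in sub.leaf_node_iter():
        host = leaf.taxon.label
        if cfg.host_switch_prob > 0 and rng.random() < cfg.host_switch_prob:
            others = [h for h in hosts if h != host]
            host = others[int(rng.integers(len(others)))]
        assoc[leaf] = host
    lengths = [e.length for e in sub.preorder_edge_iter() if e.length]
    within = 0.05 * float(np.median(lengths)) if lengths else 0.01
    taxa = sub.taxon_namespace
    links = []
    for j, leaf in enumerate(list(sub.leaf_node_iter())):
        host = assoc[leaf]
        leaf.taxon = None
        if cfg.mags_per_host == 1:
            lbl = f"{clade_id}_h{j}_m1"
            leaf.taxon = taxa.new_taxon(lbl)
            links.append((lbl, host))
        else:
            for m in range(cfg.mags_per_host):
                lbl = f"{clade_id}_h{j}_m{m + 1}"
                child = leaf.new_child()
                child.taxon = taxa.new_taxon(lbl)
                child.edge.length = within * (1.0 + 0.1 * rng.random())
                links.append((lbl, host))
    return sub, links


def simulate_random_clade(host_tree, cfg: SimConfig, rng_seed=0, clade_id="r0",
                          n_symbionts: int = 7, depth_scale: float = 1.0,
                          min_hosts: int = 3):
    """A null clade: an independent Yule symbiont tree with hosts assigned
    uniformly at random (resampled until >= min_hosts species appear)."""
    rng = as_rng(rng_seed)
    labels = [f"{clade_id}_t{j + 1}" for j in range(n_symbionts)]
    tree = _yule_tree(n_symbionts, labels, rng)
    span = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if span > 0:
        scale = depth_scale / span
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    hosts = [l.taxon.label for l in host_tree.leaf_node_iter()]
    while True:
        assign = [hosts[int(i)] for i in rng.integers(len(hosts), size=n_symbionts)]
        if len(set(assign)) >= min_hosts:
            break
    return tree, list(zip(labels, assign))


def _graft(clades, stem_length: float) -> dendropy.Tree:
    """Join clade trees on a star backbone with long stems."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    for sub in clades:
        node = sub.seed_node
        tree.seed_node.add_child(node)
        node.edge.length = stem_length
        for leaf in node.leaf_iter():
            leaf.taxon = taxa.new_taxon(leaf.taxon.label)
    return tree


def simulate_scan_dataset(cfg: SimConfig, rng_seed=None) -> ScanDataset:
    """A full scan input: a MAG tree with ``n_codiv_clades`` planted
    host-tracking clades and ``n_random_clades`` independent clades hung on
    a deep star backbone, plus tip metadata and ground truth.

    Stems are long enough that only within-clade nodes fall in the distal
    quarter of the tree span, mirroring the restriction of the scan to
    shallow clades.
    """
    rng = as_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    host_tree = simulate_host_tree(cfg, rng)
    clades, truth = [], {}
    for i in range(cfg.n_codiv_clades):
        cid = f"codiv{i + 1}"
        sub, links = simulate_codiv_clade(host_tree, cfg, rng, clade_id=cid)
        clades.append((cid, "codiv", sub, links))
    for i in range(cfg.n_random_clades):
        cid = f"rand{i + 1}"
        sub, links = simulate_random_clade(host_tree, cfg, rng, clade_id=cid)
        clades.append((cid, "random", sub, links))
    spans = []
    for _, _, sub, _ in clades:
        depths = [l.distance_from_root() for l in sub.leaf_node_iter()]
        spans.append(2 * max(depths))
    stem = 3.0 * max(spans)
    tree = _graft([sub for _, _, sub, _ in clades], stem)
    rows = []
    for cid, kind, _, links in clades:
        for tip, host in links:
            rows.append({"tip_id": tip, "host_species": host,
                         "host_category": "other", "taxonomy": cid})
        truth[cid] = {"type": kind, "tips": [t for t, _ in links]}
    meta = pd.DataFrame(rows).set_index("tip_id")
    return ScanDataset(tree=tree, host_tree=host_tree, meta=meta,
                       ground_truth=truth)


# ---------------------------------------------------------------------------
# Codon alignments


_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate_sequence(codons, t, omega, kappa, rng):
    """Evolve a codon list along a branch; returns (codons, nd_true, sd_true).

    The branch length t is the expected number of attempted mutations per
    nucleotide site. Attempts pick a site uniformly and a target base with
    transition:transversion odds kappa:1; changes creating stop codons are
    rejected, nonsynonymous changes are accepted with probability omega.
    """
    codons = list(codons)
    n_nt = 3 * len(codons)
    nd = sd = 0
    n_attempts = rng.poisson(n_nt * t)
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_attempts):
        site = int(rng.integers(n_nt))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        old = codon[pos]
        if rng.random() < p_ts:
            new = _TS[old]
        else:
            tv = [b for b in BASES if b != old and b != _TS[old]]
            new = tv[int(rng.integers(2))]
        mut = codon[:pos] + new + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        if translate(mut) != translate(codon):
            # relative acceptance omega:1 for nonsynonymous vs synonymous
            if omega < 1.0 and rng.random() >= omega:
                continue
            nd += 1
        else:
            if omega > 1.0 and rng.random() >= 1.0 / omega:
                continue
            sd += 1
        codons[ci] = mut
    return codons, nd, sd


def simulate_codon_alignment(tree, tip_group: dict, cfg: SimConfig, rng_seed=0,
                             gene_id="gene", omega_other: float = None):
    """Simulate a codon alignment on a gene tree with class-specific omega.

    Terminal branches take the omega of their tip's group (``omega_lab`` /
    ``omega_wild`` / ``omega_other``, the latter defaulting to the
    lab/wild geometric mean); internal branches use ``omega_other``. The
    root sequence is uniform over sense codons; substitutions accumulate by
    rejection against omega, a mechanism independent of the counting
    estimator.

    Returns ``(GeneFamily, truth)`` where truth maps tip label to the true
    per-branch (nonsynonymous, synonymous) substitution counts and omegas.
    """
    rng = as_rng(rng_seed)
    if omega_other is None:
        omega_other = float(np.sqrt(cfg.omega_lab * cfg.omega_wild))
    omegas = {"lab": cfg.omega_lab, "wild": cfg.omega_wild, "other": omega_other}
    L = cfg.gene_length_codons
    root_seq = [SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=L)]
    seqs = {}
    truth = {"branch_counts": {}, "omega": dict(omegas)}
    state = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if node.is_leaf():
            grp = tip_group.get(node.taxon.label, "other")
        else:
            grp = "other"
        evolved, nd, sd = _mutate_sequence(
            state[node.parent_node], t, omegas[grp], cfg.kappa, rng
        )
        state[node] = evolved
        if node.is_leaf():
            lbl = node.taxon.label
            seqs[lbl] = "".join(evolved)
            truth["branch_counts"][lbl] = {"nd": nd, "sd": sd, "group": grp}
    fam = GeneFamily(gene_id=gene_id, alignment=seqs, gene_tree=tree,
                     tip_group=dict(tip_group))
    return fam, truth


def _balanced_gene_tree(n_lab: int, n_wild: int, branch_length: float):
    """Two sister groups (lab, wild) of tips, a shape typical of the
    reciprocally monophyletic lab/wild strains within ancestral clades."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    groups = {}
    for grp, n in (("lab", n_lab), ("wild", n_wild)):
        anc = tree.seed_node.new_child()
        anc.edge.length = branch_length
        for i in range(n):
            tip = anc.new_child()
            lbl = f"{grp}{i + 1}"
            tip.taxon = taxa.new_taxon(lbl)
            tip.edge.length = branch_length
            groups[lbl] = grp
    return tree, groups


def simulate_gene_families(cfg: SimConfig, n_genes: int, rng_seed=0,
                           n_lab: int = 2, n_wild: int = 2,
                           branch_length: float = 0.05):
    """A batch of gene families on a fixed lab/wild sister-group tree.

    Yields ``(GeneFamily, truth)`` pairs; seeds are derived per gene so the
    batch is reproducible and order-independent.
    """
    base = np.random.SeedSequence(entropy=int(rng_seed))
    out = []
    for g, child in enumerate(base.spawn(n_genes)):
        tree, groups = _balanced_gene_tree(n_lab, n_wild, branch_length)
        fam, truth = simulate_codon_alignment(
            tree, groups, cfg, rng_seed=np.random.default_rng(child),
            gene_id=f"gene{g + 1}",
        )
        out.append((fam, truth))
    return out


# ---------------------------------------------------------------------------
# Competition experiment


def simulate_competition_table(cfg: SimConfig, rng_seed=None, n_wildling: int = 4,
                               n_lab: int = 4, n_gf: int = 6, days=range(1, 18),
                               n_diag_per_source: int = 52, n_shared: int = 2536,
                               codiv_genera=("g_codiv1", "g_codiv2", "g_codiv3", "g_codiv4")):
    """Simulate the co-housing experiment's ASV table.

    Wildling and laboratory source communities carry disjoint diagnostic
    ASVs within co-diversified genera plus shared background ASVs in a
    non-co-diversified genus. Each germ-free (GF) mouse's community on day
    t is a multinomial draw from a mixture of the two source profiles whose
    wildling weight follows logistic growth with slope ``advantage``
    centered at day 4 (``advantage=0`` keeps the mixture at 1/2 throughout).

    The defaults mirror the scale of a rarefied 16S co-housing dataset
    (~2,600 ASVs, ~100 diagnostic, depth 40,000 reads), so rare ASVs sit
    near the detection limit and presence/absence profiles carry sampling
    noise, as the Dice analyses assume.

    Returns ``(table, meta, taxonomy, diagnostic_truth)``.
    """
    rng = as_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    asvs, tax = [], {}
    for k in range(n_diag_per_source):
        a = f"asv_w{k + 1}"
        asvs.append(a)
        tax[a] = codiv_genera[k % len(codiv_genera)]
    for k in range(n_diag_per_source):
        a = f"asv_l{k + 1}"
        asvs.append(a)
        tax[a] = codiv_genera[k % len(codiv_genera)]
    for k in range(n_shared):
        a = f"asv_bg{k + 1}"
        asvs.append(a)
        tax[a] = "g_background"
    n_asv = len(asvs)
    w_slice = slice(0, n_diag_per_source)
    l_slice = slice(n_diag_per_source, 2 * n_diag_per_source)
    bg_slice = slice(2 * n_diag_per_source, n_asv)

    # matched abundance structure: the two sources carry disjoint diagnostic
    # ASVs but identical weight vectors, so with advantage=0 the design is
    # exactly symmetric and colonization dynamics are the only signal
    diag_weights = rng.lognormal(0.0, 1.5, size=n_diag_per_source)
    bg_weights = rng.lognormal(0.0, 1.5, size=n_shared)

    def profile(active_slice):
        p = np.zeros(n_asv)
        p[active_slice] = diag_weights
        p[bg_slice] = bg_weights
        return p / p.sum()

    p_wild = profile(w_slice)
    p_lab = profile(l_slice)
    rows, meta_rows = [], []

    def add_sample(sample, mouse, group, day, probs):
        rows.append(rng.multinomial(cfg.depth, probs))
        meta_rows.append({"sample": sample, "mouse_id": mouse,
                          "group": group, "day": day})

    for m in range(n_wildling):
        add_sample(f"W{m + 1}_d0", f"wildling_{m + 1}", "wildling", 0, p_wild)
    for m in range(n_lab):
        add_sample(f"L{m + 1}_d0", f"lab_{m + 1}", "lab", 0, p_lab)
    for m in range(n_gf):
        for day in days:
            w = 1.0 / (1.0 + np.exp(-cfg.advantage * (day - 4.0)))
            probs = w * p_wild + (1.0 - w) * p_lab
            add_sample(f"GF{m + 1}_d{day}", f"gf_{m + 1}", "GF", int(day), probs)

    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = pd.DataFrame(np.vstack(rows), index=meta.index, columns=asvs)
    taxonomy = pd.Series(tax)
    truth = pd.Series(
        {**{a: "wildling_derived" for a in asvs[w_slice]},
         **{a: "lab_derived" for a in asvs[l_slice]}},
        dtype=object,
    ).sort_index()
    return table, meta, taxonomy, truth


# ---------------------------------------------------------------------------
# Serialization helpers for the CLI


def write_scan_dataset(ds: ScanDataset, outdir) -> None:
    from pathlib import Path

    from .phylo import write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_newick(ds.tree, outdir / "mags.nwk")
    write_newick(ds.host_tree, outdir / "hosts.nwk")
    ds.meta.to_csv(outdir / "tips.tsv", sep="\t")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ds.ground_truth, fh, indent=1, sort_keys=True)


def config_from_mapping(mapping: dict) -> SimConfig:
    known = set(SimConfig.__dataclass_fields__)
    bad = set(mapping) - known
    if bad:
        raise ValueError(f"unknown SimConfig fields: {sorted(bad)}")
    return SimConfig(**mapping)


def config_to_mapping(cfg: SimConfig) -> dict:
    return asdict(cfg)
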