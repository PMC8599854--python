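"""Genomic intratumor heterogeneity: trunk/branch/private structure,
parsimony phylogenies, CCF estimation and clonal architecture.

Conventions
-----------
A tumor's mutation profile is a binary matrix: rows are distinct mutations
(the union over regions), columns are regions, entry 1 iff the mutation was
detected in that region. A mutation present in all regions is *trunk*, in
exactly one region *private*, otherwise *branch*. Phylogenies are rooted at
the germline (an implicit all-zero taxon) and built by exhaustive Wagner
parsimony over rooted binary topologies — exact at the 2-3 regions per tumor
typical of multi-region studies, bounded at 8 regions.

Cancer-cell fractions (CCF) convert a variant-allele fraction into the
fraction of tumor cells carrying the mutation, adjusting for tumor purity p,
local total copy number c and mutation multiplicity m:

    ccf = vaf * (p*c + (1-p)*2) / (p*m)

Clonal architecture is a deliberate simplification of Dirichlet-process
CCF clustering: a one-dimensional Gaussian mixture with BIC model selection;
the clonal/subclonal call keeps the standard rule (a mutation is clonal iff
it sits in the cluster with the highest cellular prevalence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

MAX_REGIONS_EXHAUSTIVE = 8


# ---------------------------------------------------------------------------
# mutation matrix

def mutation_matrix(variants: pd.DataFrame, regions: list[str] | None = None) -> pd.DataFrame:
    """Binary mutation-by-region matrix for one tumor.

    ``variants`` needs columns region_id, chrom, pos, ref, alt. Rows are
    indexed by "chrom:pos:ref>alt" keys; columns are the tumor's regions.
    """
    keys = (
        variants["chrom"].astype(str)
        + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"].astype(str)
        + ">" + variants["alt"].astype(str)
    )
    df = pd.DataFrame({"key": keys, "region": variants["region_id"].astype(str), "x": 1})
    mat = df.pivot_table(index="key", columns="region", values="x", aggfunc="max", fill_value=0)
    if regions is not None:
        mat = mat.reindex(columns=[str(r) for r in regions], fill_value=0)
    mat = mat[(mat.sum(axis=1) > 0)]
    return mat.astype(int)


def classify_trunk_branch_private(matrix: pd.DataFrame) -> pd.DataFrame:
    """Label each mutation trunk / branch / private.

    Single-region tumors are all-trunk by convention and flagged as excluded
    from ITH summaries (the ``excluded_from_ith`` column).
    """
    n_regions = matrix.shape[1]
    counts = matrix.sum(axis=1)
    if n_regions == 1:
        lab = pd.Series("trunk", index=matrix.index)
    else:
        lab = pd.Series("branch", index=matrix.index)
        lab[counts == n_regions] = "trunk"
        lab[counts == 1] = "private"
    out = pd.DataFrame({"label": lab, "n_regions_present": counts})
    out["excluded_from_ith"] = n_regions == 1
    return out


def trunk_fraction(matrix: pd.DataFrame) -> float:
    labels = classify_trunk_branch_private(matrix)["label"]
    return float((labels == "trunk").mean())


def mutational_jaccard(matrix: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise region Jaccard indices over mutation sets, plus their mean.

    Returns an empty frame and NaN mean for single-region tumors.
    """
    regions = list(matrix.columns)
    rows = []
    for a, b in itertools.combinations(regions, 2):
        sa, sb = matrix[a].astype(bool), matrix[b].astype(bool)
        union = int((sa | sb).sum())
        ji = float((sa & sb).sum() / union) if union else np.nan
        rows.append({"region_a": a, "region_b": b, "jaccard": ji})
    df = pd.DataFrame(rows, columns=["region_a", "region_b", "jaccard"])
    mean = float(df["jaccard"].mean()) if len(df) else float("nan")
    return df, mean


# ---------------------------------------------------------------------------
# Wagner parsimony with germline root

@dataclass
class PhyloTree:
    """A rooted parsimony tree; the root is the (all-zero) germline.

    ``topology`` is a nested-tuple encoding of the subtree below the trunk
    edge; ``edge_counts`` maps an edge id (the canonical encoding of the
    clade below it) to the number of mutations assigned to that edge. The
    trunk edge is the edge from the germline to the common ancestor of all
    regions.
    """

    regions: list[str]
    topology: object
    total_length: int
    trunk_count: int
    edge_counts: dict = field(default_factory=dict)

    @property
    def trunk_fraction(self) -> float:
        return self.trunk_count / self.total_length if self.total_length else float("nan")

    def newick(self) -> str:
        def enc(node):
            if isinstance(node, str):
                return f"{node}:{self.edge_counts.get(_canon(node), 0)}"
            inner = ",".join(enc(c) for c in node)
            return f"({inner}):{self.edge_counts.get(_canon(node), 0)}"

        return f"(germline:0,{enc(self.topology)});"


def _canon(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_canon(c) for c in node)) + ")"


def _rooted_topologies(leaves: list[str]):
    """All rooted binary topologies over the leaves, as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _rooted_topologies(rest):
        yield from _insert(sub, first)


def _insert(tree, leaf):
    # attach above the current (sub)root
    yield (leaf, tree)
    if not isinstance(tree, str):
        left, right = tree
        for new_left in _insert(left, leaf):
            yield (new_left, right)
        for new_right in _insert(right, leaf):
            yield (left, new_right)


def _sankoff_cost(tree, states: dict[str, int]) -> np.ndarray:
    """Min change counts for subtree root state 0/1 (binary character)."""
    if isinstance(tree, str):
        s = states[tree]
        return np.array([0 if s == 0 else np.inf, 0 if s == 1 else np.inf])
    left = _sankoff_cost(tree[0], states)
    right = _sankoff_cost(tree[1], states)
    out = np.empty(2)
    for s in (0, 1):
        out[s] = min(left[t] + (s != t) for t in (0, 1)) + min(
            right[t] + (s != t) for t in (0, 1)
        )
    return out


def _assign_changes(tree, states: dict[str, int], parent_state: int, changed: list):
    """Top-down assignment; prefer the parent state on ties (delayed changes)."""
    cost = _sankoff_cost(tree, states)
    totals = [cost[s] + (s != parent_state) for s in (0, 1)]
    if totals[parent_state] <= totals[1 - parent_state]:
        s = parent_state
    else:
        s = 1 - parent_state
    if s != parent_state:
        changed.append(_canon(tree))
    if not isinstance(tree, str):
        for child in tree:
            _assign_changes(child, states, s, changed)


def build_parsimony_tree(matrix: pd.DataFrame) -> PhyloTree:
    """Minimum-length rooted tree under Wagner parsimony, germline root.

    Exhaustive over rooted binary topologies (ties broken by the
    lexicographically smallest canonical topology encoding). Each mutation
    is then placed on the edges where its state changes under a delayed
    (parent-state-preferring) assignment; reversals are allowed.
    """
    regions = [str(c) for c in matrix.columns]
    if len(regions) > MAX_REGIONS_EXHAUSTIVE:
        raise ValueError(
            f"{len(regions)} regions exceeds the exhaustive-search bound "
            f"({MAX_REGIONS_EXHAUSTIVE}); a heuristic search is out of scope"
        )
    chars = matrix.values.astype(int)
    best = None
    if len(regions) == 1:
        topo = regions[0]
        length = int(chars.sum())
        counts = {regions[0]: length}
        return PhyloTree(regions, topo, length, length, counts)
    for topo in _rooted_topologies(regions):
        length = 0
        for row in chars:
            states = dict(zip(regions, row))
            cost = _sankoff_cost(topo, states)
            length += int(min(cost[0], cost[1] + 1))
        key = (length, _canon(topo))
        if best is None or key < best[0]:
            best = (key, topo)
    (length, _), topo = best
    edge_counts: dict[str, int] = {}
    for row in chars:
        states = dict(zip(regions, row))
        changed: list[str] = []
        _assign_changes(topo, states, 0, changed)
        for edge in changed:
            edge_counts[edge] = edge_counts.get(edge, 0) + 1
    trunk = edge_counts.get(_canon(topo), 0)
    return PhyloTree(regions, topo, int(length), int(trunk), edge_counts)


# ---------------------------------------------------------------------------
# CCF and clonal architecture

def estimate_ccf(
    vaf: float, purity: float, local_cn: int = 2, multiplicity: int = 1
) -> tuple[float, float]:
    """Cancer-cell fraction from VAF, purity, local CN and multiplicity.

    Returns (clamped ccf in [0,1], raw unclamped value).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if local_cn < 1 or multiplicity < 1:
        raise ValueError("local_cn and multiplicity must be >= 1")
    raw = vaf * (purity * local_cn + (1 - purity) * 2) / (purity * multiplicity)
    return float(np.clip(raw, 0.0, 1.0)), float(raw)


def infer_multiplicity(vaf: float, purity: float, local_cn: int, a_count: int) -> int:
    """Default multiplicity rule: 1 unless the implied CCF exceeds 1 and the
    major allele carries >1 copy, in which case round the implied value,
    capped at the major-allele count."""
    if a_count <= 1:
        return 1
    implied = vaf * (purity * local_cn + (1 - purity) * 2) / purity
    if implied > 1:
        return int(min(max(1, round(implied)), a_count))
    return 1


def merge_regions(variants: pd.DataFrame) -> pd.DataFrame:
    """Tumor-level merge: sum alt and total reads per locus across regions
    (emulating merged alignments), recompute VAF and keep the max LOD."""
    keys = ["patient_id", "chrom", "pos", "ref", "alt"]
    agg = {"t_alt": "sum", "t_depth": "sum", "lod": "max"}
    keep = [c for c in ("gene", "func_class", "tnc", "cadd") if c in variants.columns]
    merged = variants.groupby(keys, as_index=False).agg(
        {**agg, **{c: "first" for c in keep}}
    )
    merged["t_vaf"] = np.where(merged["t_depth"] > 0, merged["t_alt"] / merged["t_depth"], 0.0)
    return merged


@dataclass
class ClonalArchitecture:
    assignments: pd.DataFrame  # columns: ccf, cluster_id, clonal
    cluster_prevalence: pd.Series
    clonal_fraction: float
    k: int
    fallback: bool = False  # too few mutations for mixture selection


def cluster_clonal_architecture(
    ccf: np.ndarray | pd.Series, k_max: int = 5, min_mutations: int = 5
) -> ClonalArchitecture:
    """BIC-selected 1-D Gaussian-mixture clustering of CCF values.

    Cluster prevalence is the cluster mean CCF; mutations in the cluster of
    highest prevalence are clonal. Fewer than ``min_mutations`` values fall
    back to a single flagged cluster.

    Pass the *raw* (unclamped) CCF values: clamping to 1 creates a point
    mass that a Gaussian mixture will split into a spurious spike cluster.
    """
    x = np.asarray(ccf, dtype=float).reshape(-1, 1)
    idx = ccf.index if isinstance(ccf, pd.Series) else pd.RangeIndex(len(x))
    if len(x) < min_mutations:
        df = pd.DataFrame({"ccf": x.ravel(), "cluster_id": 0, "clonal": True}, index=idx)
        prev = pd.Series([float(x.mean())] if len(x) else [], name="prevalence")
        return ClonalArchitecture(df, prev, 1.0 if len(x) else float("nan"), 1, fallback=True)
    best = None
    for k in range(1, k_max + 1):
        if k > len(np.unique(x.ravel())):
            break
        gm = GaussianMixture(n_components=k, random_state=0, n_init=3, reg_covar=1e-5)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, gm)
    _, k, gm = best
    labels = gm.predict(x)
    means = gm.means_.ravel()
    order = np.argsort(-means)  # cluster 0 = highest prevalence
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    prev = pd.Series(means[order], name="prevalence")
    df = pd.DataFrame(
        {"ccf": x.ravel(), "cluster_id": labels, "clonal": labels == 0}, index=idx
    )
    return ClonalArchitecture(df, prev, float((labels == 0).mean()), k)
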