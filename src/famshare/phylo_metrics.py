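"""Phylogenetic community metrics: UniFrac, Faith's PD, rarefaction, PCoA.

All phylogenetic quantities are computed from a :class:`BranchPartition`:
for every branch of the rooted tree we record its length and which OTUs
descend from it.  Presence or abundance of a branch in a sample then
reduces to matrix products against the count table, which makes whole
distance matrices cheap.

Conventions (stated because implementations differ):

* presence for unweighted UniFrac is count >= 1 (applied after
  rarefaction upstream; no relative-abundance floor);
* weighted UniFrac defaults to the raw (unnormalized) variant; the
  normalized variant divides by the abundance-weighted root-to-tip
  depth sum;
* Faith's PD includes the path from the root to the observed subtree;
* rarefaction subsamples without replacement (multivariate
  hypergeometric) and derives each sample's random stream from the
  global seed plus a hash of the sample id, so results do not depend on
  sample order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.linalg import eigh
from skbio import DistanceMatrix, TreeNode

from .io_formats import OtuTable

__all__ = [
    "BranchPartition",
    "filter_by_depth",
    "rarefy",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unweighted_unifrac_matrix",
    "weighted_unifrac_matrix",
    "faith_pd",
    "faith_pd_all",
    "rarefaction_curve",
    "pcoa",
    "PcoaResult",
]


# ---------------------------------------------------------------------------
# Branch partition
# ---------------------------------------------------------------------------

@dataclass
class BranchPartition:
    """Per-branch lengths and descendant-OTU membership for a tree.

    ``membership[e, k]`` is True when OTU ``k`` (in the order of the table
    it was built against) is a descendant tip of branch ``e``.  The root
    itself carries no branch.
    """

    lengths: np.ndarray          # (n_edges,)
    membership: np.ndarray       # (n_edges, n_otus) bool
    otu_ids: list[str]
    tip_depths: np.ndarray       # (n_otus,) root-to-tip distance per OTU

    @classmethod
    def from_tree(cls, tree: TreeNode, otu_ids: Sequence[str]) -> "BranchPartition":
        otu_index = {name: i for i, name in enumerate(otu_ids)}
        nodes = list(tree.postorder(include_self=False))
        lengths = np.empty(len(nodes))
        membership = np.zeros((len(nodes), len(otu_ids)), dtype=bool)
        node_row = {}
        for e, node in enumerate(nodes):
            lengths[e] = node.length if node.length is not None else 0.0
            node_row[id(node)] = e
            if node.is_tip():
                if node.name not in otu_index:
                    raise ValueError(
                        f"tree tip {node.name!r} not among the table's OTU ids")
                membership[e, otu_index[node.name]] = True
            else:
                for child in node.children:
                    membership[e] |= membership[node_row[id(child)]]
        covered = membership.any(axis=0)
        if len(nodes) and not covered.all():
            absent = [otu_ids[i] for i in np.nonzero(~covered)[0][:5]]
            raise ValueError(f"OTU id(s) missing from tree tips: {absent}")
        depths = (lengths[:, None] * membership).sum(axis=0)
        return cls(lengths, membership, list(otu_ids), depths)

    def branch_presence(self, presence: np.ndarray) -> np.ndarray:
        """(n_edges, n_samples) indicator: any descendant tip present."""
        return (self.membership @ presence) > 0

    def branch_proportions(self, rel_abundance: np.ndarray) -> np.ndarray:
        """(n_edges, n_samples) proportion of reads descending each branch."""
        return self.membership @ rel_abundance


def _partition_for(table: OtuTable, tree: TreeNode) -> BranchPartition:
    return BranchPartition.from_tree(tree, table.otu_ids)


# ---------------------------------------------------------------------------
# Depth filtering and rarefaction
# ---------------------------------------------------------------------------

def filter_by_depth(table: OtuTable, min_depth: int) -> OtuTable:
    """Drop samples with fewer than ``min_depth`` total reads.

    All-zero OTU rows are retained; presence/absence is decided
    downstream.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    keep = table.depths() >= min_depth
    ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return table.select_samples(ids)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stream keyed by (seed, crc32(sample id)) so results are independent
    # of the order samples appear in the table
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement."""
    depths = table.depths()
    for sid, d in zip(table.sample_ids, depths):
        if d < depth:
            raise ValueError(f"sample {sid!r} has {d} reads, fewer than depth {depth}")
    out = np.empty_like(table.counts)
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            rng = _sample_rng(seed, sid)
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(list(table.otu_ids), list(table.sample_ids), out,
                    None if table.taxonomy is None else list(table.taxonomy))


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _unweighted_from_vectors(lengths, a_i, a_j):
    union = float(lengths[a_i | a_j].sum())
    if union == 0.0:
        raise ValueError("both samples are empty; unweighted UniFrac undefined")
    unique = float(lengths[a_i ^ a_j].sum())
    return unique / union


def unweighted_unifrac(table: OtuTable, tree: TreeNode,
                       sample_i: str, sample_j: str,
                       partition: Optional[BranchPartition] = None) -> float:
    """Fraction of observed branch length unique to one of the two samples."""
    part = partition or _partition_for(table, tree)
    pres = table.presence()
    a = part.branch_presence(pres[:, [table.sample_index(sample_i),
                                      table.sample_index(sample_j)]])
    return _unweighted_from_vectors(part.lengths, a[:, 0], a[:, 1])


def weighted_unifrac(table: OtuTable, tree: TreeNode,
                     sample_i: str, sample_j: str, normalized: bool = False,
                     partition: Optional[BranchPartition] = None) -> float:
    """Abundance-weighted UniFrac; raw by default, optionally normalized."""
    part = partition or _partition_for(table, tree)
    ii, jj = table.sample_index(sample_i), table.sample_index(sample_j)
    depths = table.depths()
    if depths[ii] == 0 or depths[jj] == 0:
        raise ValueError("weighted UniFrac undefined for an empty sample")
    rel = table.relative_abundance()[:, [ii, jj]]
    p = part.branch_proportions(rel)
    raw = float((part.lengths * np.abs(p[:, 0] - p[:, 1])).sum())
    if not normalized:
        return raw
    denom = float((part.tip_depths * (rel[:, 0] + rel[:, 1])).sum())
    if denom == 0.0:
        raise ValueError("normalization denominator is zero")
    return raw / denom


def unweighted_unifrac_matrix(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """All-pairs unweighted UniFrac (empty samples are an error)."""
    part = _partition_for(table, tree)
    if np.any(table.depths() == 0):
        empties = [s for s, d in zip(table.sample_ids, table.depths()) if d == 0]
        raise ValueError(f"empty sample(s): {empties[:5]}")
    a = part.branch_presence(table.presence()).astype(float)
    la = part.lengths[:, None] * a
    s = la.sum(axis=0)                       # per-sample observed branch length
    both = la.T @ a                          # shared observed branch length
    union = s[:, None] + s[None, :] - both
    xor = s[:, None] + s[None, :] - 2.0 * both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, xor / union, 0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(d, table.sample_ids)


def weighted_unifrac_matrix(table: OtuTable, tree: TreeNode,
                            normalized: bool = False) -> DistanceMatrix:
    part = _partition_for(table, tree)
    if np.any(table.depths() == 0):
        empties = [s for s, d in zip(table.sample_ids, table.depths()) if d == 0]
        raise ValueError(f"empty sample(s): {empties[:5]}")
    rel = table.relative_abundance()
    p = part.branch_proportions(rel)         # (n_edges, n_samples)
    n = table.n_samples
    d = np.zeros((n, n))
    lp = part.lengths[:, None]
    for i in range(n):
        diff = np.abs(p[:, i:i + 1] - p[:, i + 1:])
        d[i, i + 1:] = (lp * diff).sum(axis=0)
    d = d + d.T
    if normalized:
        depth_mass = part.tip_depths @ rel   # per sample
        denom = depth_mass[:, None] + depth_mass[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, d / denom, 0.0)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.sample_ids)


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------

def faith_pd(table: OtuTable, tree: TreeNode, sample: str,
             partition: Optional[BranchPartition] = None) -> float:
    """Total branch length of the root-inclusive subtree spanning observed OTUs."""
    part = partition or _partition_for(table, tree)
    pres = table.presence()[:, [table.sample_index(sample)]]
    if not pres.any():
        warnings.warn(f"sample {sample!r} is empty; PD = 0", stacklevel=2)
        return 0.0
    a = part.branch_presence(pres)[:, 0]
    return float(part.lengths[a].sum())


def faith_pd_all(table: OtuTable, tree: TreeNode) -> dict[str, float]:
    part = _partition_for(table, tree)
    a = part.branch_presence(table.presence())
    pd_vals = (part.lengths[:, None] * a).sum(axis=0)
    return dict(zip(table.sample_ids, map(float, pd_vals)))


def rarefaction_curve(table: OtuTable, tree: TreeNode, depths: Sequence[int],
                      n_iter: int, seed: int):
    """Mean +/- 95% CI of Faith's PD over repeated rarefactions.

    Returns ``{sample_id: {depth: (mean, half_ci)}}``; depths exceeding a
    sample's total are skipped for that sample.
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be ascending")
    part = _partition_for(table, tree)
    totals = table.depths()
    out: dict[str, dict[int, tuple[float, float]]] = {s: {} for s in table.sample_ids}
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rng = _sample_rng(seed, sid)
        for depth in depths:
            if depth > totals[j]:
                continue
            vals = np.empty(n_iter)
            for it in range(n_iter):
                sub = col if totals[j] == depth else \
                    rng.multivariate_hypergeometric(col, depth)
                a = part.branch_presence((sub >= 1)[:, None])[:, 0]
                vals[it] = part.lengths[a].sum()
            mean = float(vals.mean())
            half = float(1.96 * vals.std(ddof=1) / np.sqrt(n_iter)) if n_iter > 1 else 0.0
            out[sid][depth] = (mean, half)
    return out


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray      # (n_samples, n_axes) for positive eigenvalues
    eigenvalues: np.ndarray      # all eigenvalues, descending
    sample_ids: list[str]

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0, None)
        total = pos.sum()
        return pos / total if total > 0 else pos


def pcoa(matrix: DistanceMatrix, n_axes: Optional[int] = None) -> PcoaResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-center -1/2 J D^2 J, eigendecompose, and scale eigenvectors by
    sqrt(eigenvalue).  Negative eigenvalues are reported but contribute
    no coordinates; requesting more axes than there are positive
    eigenvalues truncates with a warning.
    """
    d = matrix.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0)) if n else 0.0
    n_pos = int((vals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalue(s); truncating "
                      f"requested {n_axes} axes", stacklevel=2)
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(np.clip(vals[:n_axes], 0, None))
    return PcoaResult(coords, vals, list(matrix.ids))
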