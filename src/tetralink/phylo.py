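"""Rao quadratic-entropy phylogenetic dissimilarity between communities.

Given an (approximately) ultrametric rooted tree over OTUs and a site x
OTU relative-abundance table, the expected patristic distance between two
individuals drawn from communities k and l is

    D_kl = sum_i sum_j p_ik p_jl d_ij,

with d_ij the tip-to-tip path length.  The among-community dissimilarity
returned by default is Rao's discriminant form

    H_kl = D_kl - (D_kk + D_ll) / 2,

which is zero for identical communities and, on ultrametric trees,
non-negative.  The raw between-community expectation D is available
behind a flag since community-phylogenetics programs differ in which of
the two they print.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import AlignmentError, FormatError, ValidationError

__all__ = [
    "Phylogeny",
    "CommunityTable",
    "read_tree",
    "cophenetic",
    "rao_dissimilarity",
]

logger = logging.getLogger(__name__)

#: Relative tolerance for the ultrametricity check; rate-smoothed trees
#: carry small numerical deviations.
ULTRAMETRIC_RTOL = 1e-3


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy Tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def root_distances(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=True
        )
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self.tree.leaf_node_iter()
        }

    @property
    def is_ultrametric(self) -> bool:
        depths = np.array(list(self.root_distances().values()))
        span = float(depths.max() - depths.min())
        return span <= ULTRAMETRIC_RTOL * max(float(depths.max()), 1e-12)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write(self, path: str | PathLike) -> None:
        Path(path).write_text(self.newick() + "\n")


def _check_tree(tree: dendropy.Tree) -> Phylogeny:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    phy = Phylogeny(tree=tree)
    if not phy.is_ultrametric:
        warnings.warn(
            "tree is not ultrametric within tolerance; Rao dissimilarities "
            "may be negative for some community pairs",
            RuntimeWarning,
            stacklevel=3,
        )
    return phy


def read_tree(source: str | PathLike) -> Phylogeny:
    """Read a newick tree from a path or a newick string.

    Branch lengths are required; ultrametricity is checked and a warning
    (not an error) is emitted on violation beyond tolerance.
    """
    text = str(source)
    if "(" in text and ";" in text:
        handle: str | io.StringIO = io.StringIO(text)
    else:
        handle = io.StringIO(Path(source).read_text())
    try:
        tree = dendropy.Tree.get(
            file=handle, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"cannot parse newick tree: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise FormatError("tree has fewer than two tips")
    return _check_tree(tree)


def cophenetic(phylogeny: Phylogeny) -> pd.DataFrame:
    """Tip x tip patristic (cophenetic) distance matrix.

    Entry (i, j) is the sum of branch lengths along the path between tips
    i and j; labels follow the tree's tip order.
    """
    tree = phylogeny.tree
    pdm = tree.phylogenetic_distance_matrix()
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass(frozen=True)
class CommunityTable:
    """Site x OTU relative abundances; rows are normalized to sum to 1."""

    p: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.p.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("community abundances must be >= 0")
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            empty = self.p.index[sums <= 0].tolist()
            raise ValidationError(f"site(s) {empty} have zero total abundance")
        if not np.allclose(sums, 1.0, atol=1e-9):
            object.__setattr__(
                self,
                "p",
                pd.DataFrame(
                    values / sums[:, None],
                    index=self.p.index,
                    columns=self.p.columns,
                ),
            )

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.p.index]

    @property
    def otus(self) -> list[str]:
        return [str(o) for o in self.p.columns]

    @classmethod
    def from_tsv(cls, path: str | PathLike) -> "CommunityTable":
        """Read a site x OTU TSV; a mothur shared-file layout is accepted
        (``label``/``numOtus`` columns dropped, ``Group`` used as site id)."""
        df = pd.read_csv(path, sep="\t")
        cols_lower = {str(c).lower(): c for c in df.columns}
        if "group" in cols_lower:
            df = df.set_index(cols_lower["group"])
        else:
            df = df.set_index(df.columns[0])
        drop = [
            cols_lower[k] for k in ("label", "numotus") if k in cols_lower
        ]
        df = df.drop(columns=drop, errors="ignore").astype(float)
        df.index = df.index.astype(str)
        return cls(p=df)

    def to_tsv(self, path: str | PathLike) -> None:
        self.p.rename_axis("site").to_csv(path, sep="\t")


def rao_dissimilarity(
    phylogeny: Phylogeny,
    community: CommunityTable,
    form: Literal["discriminant", "raw"] = "discriminant",
    weighting: Literal["abundance", "presence"] = "abundance",
) -> DistanceMatrix:
    """Rao among-community phylogenetic dissimilarity.

    Every OTU in the table must be a tip of the tree; tree tips absent
    from the table are pruned (with a logged count).  ``weighting=
    "presence"`` replaces abundances with uniform weights over the OTUs
    observed at each site.  Tiny negative values from floating-point
    cancellation (> -1e-12) are clipped to zero.
    """
    otus = community.otus
    tips = set(phylogeny.tip_labels)
    missing = sorted(set(otus) - tips)
    if missing:
        raise AlignmentError(
            f"OTU(s) absent from the tree: {missing}"
        )
    extra = tips - set(otus)
    tree = phylogeny.tree
    if extra:
        logger.info("pruning %d tree tips absent from the table", len(extra))
        tree = tree.extract_tree_with_taxa_labels(otus)

    dist = cophenetic(Phylogeny(tree=tree)).loc[otus, otus].to_numpy()
    P = community.p.to_numpy(dtype=float)
    if weighting == "presence":
        pa = (P > 0).astype(float)
        P = pa / pa.sum(axis=1, keepdims=True)
    elif weighting != "abundance":
        raise ValidationError(f"unknown weighting {weighting!r}")

    D = P @ dist @ P.T  # D_kl = sum_ij p_ik p_jl d_ij
    if form == "raw":
        H = D.copy()
        np.fill_diagonal(H, 0.0)
    elif form == "discriminant":
        within = np.diag(D)
        H = D - (within[:, None] + within[None, :]) / 2.0
    else:
        raise ValidationError(f"unknown form {form!r}")

    if H.min() < -1e-12 * max(1.0, float(np.abs(dist).max())):
        warnings.warn(
            f"negative Rao dissimilarity ({H.min():.3g}); "
            "tree is likely far from ultrametric",
            RuntimeWarning,
            stacklevel=2,
        )
    H = np.clip(H, 0.0, None)
    H = (H + H.T) / 2.0
    np.fill_diagonal(H, 0.0)
    return DistanceMatrix(H, ids=community.sites)
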