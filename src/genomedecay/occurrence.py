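"""Pathway completeness, occurrence matrices over trees, focal-gene
coevolution concordance and auxotrophy prediction.

A pathway is called complete in a genome when at least a threshold
fraction (default 90%, inclusive, compared with exact rationals) of its
expected functional roles is annotated.  A bifunctional role shared by
two pathways (the phosphoribosyl-isomerase case at which histidine- and
tryptophan-like chains converge) counts toward the completeness of both:
it simply appears in both pathway definitions' expected role sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .comparative import PresenceMatrix
from .fba import ModelAnalysis
from .model import GenomeAnnotation


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    expected_roles: frozenset[str]
    completeness_threshold: Fraction = Fraction(9, 10)
    #: roles counted in multiple pathways (informational bookkeeping)
    shared_roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "expected_roles",
                           frozenset(self.expected_roles))
        object.__setattr__(self, "shared_roles", frozenset(self.shared_roles))
        thr = Fraction(self.completeness_threshold)
        object.__setattr__(self, "completeness_threshold", thr)
        if not self.expected_roles:
            raise ValueError(f"pathway {self.name!r}: no expected roles")
        if not 0 < thr <= 1:
            raise ValueError(
                f"pathway {self.name!r}: threshold {thr} outside (0, 1]")


@dataclass
class Phylogeny:
    """A rooted tree with unique leaf ids and optional named clades.

    Clade labels are taken from internal node labels of the newick input
    (so they are monophyletic by construction) and map to leaf-id sets.
    """

    tree: dendropy.Tree
    clades: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        text = Path(source).read_text() if (
            isinstance(source, Path) or
            (isinstance(source, str) and "\n" not in source
             and not source.strip().startswith("(") and Path(source).exists())
        ) else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaf_ids) != len(set(leaf_ids)):
            raise ValueError("duplicate leaf ids in tree")
        clades: dict[str, frozenset[str]] = {}
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.label:
                clades[node.label] = frozenset(
                    lf.taxon.label for lf in node.leaf_iter())
        return cls(tree=tree, clades=clades)

    @property
    def leaf_order(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clade_leaves(self, label: str) -> frozenset[str]:
        try:
            return self.clades[label]
        except KeyError:
            raise KeyError(f"no clade labeled {label!r} in tree") from None


def pathway_completeness(
    annotation: GenomeAnnotation,
    pathway: PathwayDefinition,
) -> tuple[Fraction, bool]:
    """Fraction of expected roles present and the completeness call."""
    present = len(pathway.expected_roles & annotation.roles)
    fraction = Fraction(present, len(pathway.expected_roles))
    return fraction, fraction >= pathway.completeness_threshold


def occurrence_matrix(
    annotations: Mapping[str, GenomeAnnotation] | Sequence[GenomeAnnotation],
    pathways: Sequence[PathwayDefinition],
    focal_genes: Mapping[str, str] | None = None,
    phylogeny: Phylogeny | None = None,
) -> PresenceMatrix:
    """One 0/1 column per pathway (completeness call) and per focal gene
    (role presence); rows follow tree leaf order when a phylogeny is given.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.genome_id: a for a in annotations}
    focal_genes = dict(focal_genes or {})
    if phylogeny is not None:
        order = [g for g in phylogeny.leaf_order if g in annotations]
        missing = set(annotations) - set(order)
        if missing:
            raise ValueError(
                f"genomes absent from tree: {sorted(missing)}")
    else:
        order = sorted(annotations)
    columns = [p.name for p in pathways] + sorted(focal_genes)
    rows = []
    for g in order:
        ann = annotations[g]
        row = [int(pathway_completeness(ann, p)[1]) for p in pathways]
        row += [int(focal_genes[c] in ann.roles) for c in sorted(focal_genes)]
        rows.append(row)
    df = pd.DataFrame(rows, index=order, columns=columns, dtype=int)
    return PresenceMatrix(values=df, feature_kind="pathway")


def coevolution_concordance(
    matrix: PresenceMatrix,
    focal: str,
    pathways: Sequence[str],
) -> tuple[float, dict[str, bool]]:
    """Fraction of genomes where focal-gene presence coincides with having
    at least one complete dependent pathway, plus per-leaf discordance flags.

    This concordance score is this package's own quantification of the
    "closely tracks" coevolution pattern; it is not a published statistic.
    """
    df = matrix.values
    for col in [focal, *pathways]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in matrix")
    any_pathway = df[list(pathways)].max(axis=1).astype(bool)
    focal_present = df[focal].astype(bool)
    discordant = (focal_present != any_pathway)
    concordance = 1.0 - discordant.mean()
    return float(concordance), {g: bool(v) for g, v in discordant.items()}


def predict_auxotrophies(
    analysis: ModelAnalysis,
    nutrient_pathway_map: Mapping[str, str],
) -> frozenset[str]:
    """Pathways whose end-product nutrient appears in the minimal medium.

    A biosynthetic pathway that can no longer run forces its product into
    the predicted minimal medium; the map ties each such nutrient id to the
    pathway it reports on.
    """
    return frozenset(
        pathway for nutrient, pathway in nutrient_pathway_map.items()
        if nutrient in analysis.minimal_medium.nutrients
    )
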