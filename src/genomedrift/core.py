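"""Shared domain types, readers/writers and validation glue.

Everything downstream works in three coordinate systems: a rooted phylogeny
with branch lengths in substitutions per site, in-frame codon alignments,
and a per-species trait table (sizes in bp, C-values in pg, percentages in
[0, 100]).  This module owns those containers and the I/O for the plain-text
formats they travel in (newick, FASTA, TSV).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("genomedrift")

NUCLEOTIDES = "ACGT"
GAP = "-"
CVALUE_METHODS = ("FCM", "FD", "FIA")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PNode:
    """A node of a rooted phylogeny.

    ``length`` is the length of the branch above the node (substitutions per
    site); it is 0.0 for the root.
    """

    name: str | None = None
    length: float = 0.0
    children: list["PNode"] = field(default_factory=list)
    parent: "PNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with named tips and non-negative branch lengths.

    Invariants enforced at construction: exactly one root, unique tip names,
    branch lengths >= 0.
    """

    def __init__(self, root: PNode):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a newick string (branch lengths required on non-root edges)."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"newick parse error: {exc}") from exc

        def convert(dnode, parent=None) -> PNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length
            node = PNode(name=label, length=float(length) if length else 0.0,
                         parent=parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        return cls(convert(dtree.seed_node))

    def _validate(self) -> None:
        names = [t.name for t in self.tips()]
        if any(n is None for n in names):
            raise FormatError("unnamed tip in tree")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate tip names: {dupes}")
        for node in self.postorder():
            if node.length < 0:
                raise FormatError(f"negative branch length at {node.name!r}")

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator[PNode]:
        def walk(node: PNode) -> Iterator[PNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[PNode]:
        def walk(node: PNode) -> Iterator[PNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def tips(self) -> list[PNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def n_edges(self) -> int:
        return sum(1 for n in self.postorder() if n.parent is not None)

    def find_tip(self, name: str) -> PNode:
        for tip in self.tips():
            if tip.name == name:
                return tip
        raise KeyError(name)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip name."""
        out: dict[str, float] = {}

        def walk(node: PNode, depth: float) -> None:
            depth += node.length
            if node.is_tip:
                out[node.name] = depth
            for child in node.children:
                walk(child, depth)

        walk(self.root, -self.root.length)
        return out

    # -- editing ------------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: PNode, parent=None) -> PNode:
            new = PNode(name=node.name, length=node.length, parent=parent)
            new.children = [clone(c, new) for c in node.children]
            return new

        return Phylogeny(clone(self.root))

    def prune_to(self, keep: Sequence[str]) -> "Phylogeny":
        """Tree restricted to the named tips; unary nodes are suppressed by
        summing their branch lengths, so remaining pairwise path lengths are
        preserved."""
        keep_set = set(keep)
        missing = keep_set - set(self.tip_names)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")

        def reduce(node: PNode) -> PNode | None:
            if node.is_tip:
                if node.name in keep_set:
                    return PNode(name=node.name, length=node.length)
                return None
            kept = [c for c in (reduce(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                only = kept[0]
                only.length += node.length
                return only
            new = PNode(name=node.name, length=node.length, children=kept)
            for c in kept:
                c.parent = new
            return new

        root = reduce(self.root)
        if root is None or root.is_tip:
            raise ValueError("pruning leaves fewer than 2 tips")
        root.length = 0.0
        return Phylogeny(root)

    def resolve_polytomies(self) -> "Phylogeny":
        """Binary version; multifurcations split with zero-length branches."""
        tree = self.copy()
        changed = False
        for node in list(tree.postorder()):
            while len(node.children) > 2:
                changed = True
                a = node.children.pop()
                b = node.children.pop()
                joint = PNode(length=0.0, children=[a, b], parent=node)
                a.parent = b.parent = joint
                node.children.append(joint)
        if changed:
            logger.warning("polytomies resolved with zero-length branches")
        return tree

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: PNode) -> str:
            if node.is_tip:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner})" + (node.name or "")
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Gapped, in-frame nucleotide alignment for one gene.

    Sequences are uppercase strings over ``ACGT-`` of equal length divisible
    by three; ambiguity codes are mapped to gaps at read time.
    """

    gene_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"gene {self.gene_id}: unequal sequence lengths {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise FormatError(
                f"gene {self.gene_id}: alignment length {lengths.pop()} "
                "not divisible by 3")
        for name, seq in self.sequences.items():
            bad = set(seq) - set(NUCLEOTIDES + GAP)
            if bad:
                raise FormatError(
                    f"gene {self.gene_id}, sequence {name}: "
                    f"invalid characters {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, species: str, index: int) -> str:
        return self.sequences[species][3 * index : 3 * index + 3]

    def subset(self, species: Sequence[str]) -> "CodonAlignment":
        return CodonAlignment(
            self.gene_id, {s: self.sequences[s] for s in species})


def read_codon_fasta(path, gene_id: str | None = None) -> CodonAlignment:
    """Read a FASTA codon alignment; ambiguity codes become gaps."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    seqs = {}
    for rec in records:
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record {rec.id}")
        seq = str(rec.seq).upper().replace("U", "T")
        seq = "".join(c if c in NUCLEOTIDES else GAP for c in seq)
        seqs[rec.id] = seq
    name = gene_id if gene_id is not None else _stem(path)
    return CodonAlignment(name, seqs)


def write_codon_fasta(alignment: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# Species trait table
# ---------------------------------------------------------------------------

#: numeric trait-table columns and whether each is mandatory
_NUMERIC_COLUMNS = {
    "assembly_size": True,
    "cvalue": False,
    "contig_n50": False,
    "busco_complete": False,
    "busco_duplicated": False,
    "genome_size": False,
    "te_bp": False,
    "recent_te_bp": False,
    "dnds": False,
}

_POSITIVE_BP = ("assembly_size", "contig_n50", "genome_size", "te_bp",
                "recent_te_bp")
_PERCENT = ("busco_complete", "busco_duplicated")


@dataclass
class SpeciesTraitTable:
    """Per-species trait matrix (one row per species).

    Wraps a DataFrame indexed by species id.  Known numeric columns are
    validated (bp fields positive where present, percentages within
    [0, 100], recent TE content never above total TE content); any further
    columns are treated as optional life-history traits.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dupes = sorted(self.df.index[self.df.index.duplicated()].unique())
            raise FormatError(f"duplicate species ids: {dupes}")
        for col in _POSITIVE_BP:
            if col in self.df.columns:
                bad = self.df[col].dropna() <= 0
                if bad.any():
                    raise FormatError(
                        f"non-positive {col} for "
                        f"{sorted(bad[bad].index.tolist())}")
        for col in _PERCENT:
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise FormatError(f"{col} outside [0, 100]")
        if {"te_bp", "recent_te_bp"} <= set(self.df.columns):
            both = self.df[["te_bp", "recent_te_bp"]].dropna()
            if (both["recent_te_bp"] > both["te_bp"] * (1 + 1e-12)).any():
                raise FormatError("recent_te_bp exceeds te_bp")

    @property
    def species(self) -> list[str]:
        return self.df.index.tolist()

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, species: Sequence[str]) -> "SpeciesTraitTable":
        return SpeciesTraitTable(self.df.loc[list(species)].copy())


def read_trait_table(path) -> SpeciesTraitTable:
    """Read a tab-separated trait table.

    The first column must be ``species``; empty cells are missing values.
    Non-numeric entries in numeric columns are hard errors naming the row
    and column.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "species" not in raw.columns:
        raise FormatError(f"{path}: mandatory column 'species' missing")
    for col, mandatory in _NUMERIC_COLUMNS.items():
        if mandatory and col not in raw.columns:
            raise FormatError(f"{path}: mandatory column {col!r} missing")
    df = raw.set_index("species")
    for col in df.columns:
        if col in ("cvalue_method", "cvalue_date", "clade"):
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = bad[bad].index[0]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"{col!r}, row {row!r}")
        df[col] = converted.astype(float)
    return SpeciesTraitTable(df)


def write_trait_table(table: SpeciesTraitTable, path) -> None:
    out = table.df.copy()
    out.insert(0, "species", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric cutoff used across the pipeline, with its unit.

    Defaults are the analysis' standing choices: assemblies need contig
    N50 >= 50 kb and >= 70% complete BUSCOs; genes lose species with > 10%
    insertion occupancy; per-gene terminal branches < 0.001 subst/site are
    too noisy for dN/dS; the trimmed phylogeny keeps terminal branches in
    [0.01, 1] amino-acid subst/site; "recent" TE copies are < 5% diverged
    from their consensus; the duplication screen drops species above 30%
    duplicated BUSCOs; GC3 gene sets take the 50 poorest/richest genes among
    those covering >= 95% of species; C-values convert at 0.978e9 bp/pg.
    """

    n50_min: float = 50_000.0
    busco_complete_min: float = 70.0
    insertion_frac_max: float = 0.10
    gene_branch_min: float = 0.001
    terminal_branch_min: float = 0.01
    terminal_branch_max: float = 1.0
    recent_divergence_max: float = 0.05
    duplication_max: float = 30.0
    gc3_coverage_min: float = 0.95
    gc3_set_size: int = 50
    pg_to_bp: float = 0.978e9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n50_min", "busco_complete_min", "insertion_frac_max",
                     "gene_branch_min", "terminal_branch_min",
                     "terminal_branch_max", "recent_divergence_max",
                     "duplication_max", "gc3_coverage_min", "gc3_set_size",
                     "pg_to_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.terminal_branch_min >= self.terminal_branch_max:
            raise ValueError("terminal_branch_min must be < terminal_branch_max")


# ---------------------------------------------------------------------------
# Assembly quality filter
# ---------------------------------------------------------------------------


def filter_assemblies(table: SpeciesTraitTable,
                      cfg: PipelineConfig | None = None) -> SpeciesTraitTable:
    """Keep assemblies with contig N50 >= n50_min and complete BUSCOs >=
    busco_complete_min (boundaries inclusive).  Order-preserving and
    idempotent; an empty result is allowed but warned about."""
    cfg = cfg or PipelineConfig()
    df = table.df
    for col in ("contig_n50", "busco_complete"):
        if col not in df.columns:
            raise FormatError(f"filter_assemblies requires column {col!r}")
    n50_ok = df["contig_n50"] >= cfg.n50_min
    busco_ok = df["busco_complete"] >= cfg.busco_complete_min
    logger.info(
        "filter_assemblies: removed %d by N50, %d by BUSCO completeness",
        int((~n50_ok).sum()), int((~busco_ok).sum()))
    kept = df[n50_ok & busco_ok].copy()
    if kept.empty:
        logger.warning("filter_assemblies: no assemblies pass the filters")
    return SpeciesTraitTable(kept)
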