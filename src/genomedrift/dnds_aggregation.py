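"""Gene/branch filtering and per-species dN/dS aggregation.

A species' dN (and likewise dS) aggregates its per-gene substitution
records as

    dN = sum_i K_N(i) / sum_i (O_N(i) / l(i))

where K is the mapped count on the species' terminal branch for gene i, O
the count expected under the neutralized model, and l the gene's terminal
branch length.  The formula is implemented exactly in this form; a
``counts_only`` alternative (sum K / sum O) is exposed for sensitivity
checks since the printed denominator has unusual dimensionality.

Filters applied before aggregation: species whose sequence is >10%
insertion-derived are dropped per gene; genes whose terminal branch for the
species is shorter than 0.001 substitutions/site are dropped; blacklisted
genes (e.g. deviant-topology calls from an external screen) are removed.
All filters commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GAP, CodonAlignment, Phylogeny, PipelineConfig, logger
from .codon_dnds import GeneSubstitutionRecord


@dataclass
class SpeciesDnDs:
    """Aggregated per-species substitution rates."""

    species: str
    dN: float
    dS: float
    dnds: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.dN < 0 or self.dS < 0:
            raise ValueError("rates must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def insertion_fractions(alignment: CodonAlignment) -> dict[str, float]:
    """Per-species fraction of its residues sitting in insertion columns.

    An insertion column for a focal species is one where the focal sequence
    has a residue while the majority of the other sequences are gapped; the
    fraction is over the focal sequence's residue count.
    """
    species = alignment.species
    if len(species) < 2:
        return {s: 0.0 for s in species}
    arr = np.array([list(alignment.sequences[s]) for s in species])
    is_res = arr != GAP
    n_res_others = is_res.sum(axis=0)[None, :] - is_res
    majority_gap = n_res_others < (len(species) - 1) / 2.0
    fractions = {}
    for k, sp in enumerate(species):
        n = int(is_res[k].sum())
        if n == 0:
            fractions[sp] = 0.0
            continue
        fractions[sp] = float((is_res[k] & majority_gap[k]).sum()) / n
    return fractions


def filter_insertion_heavy(alignment: CodonAlignment,
                           cfg: PipelineConfig | None = None) -> CodonAlignment:
    """Drop species with strictly more than ``insertion_frac_max`` of their
    sequence occupied by insertions (boundary retained)."""
    cfg = cfg or PipelineConfig()
    fracs = insertion_fractions(alignment)
    keep = [s for s in alignment.species
            if fracs[s] <= cfg.insertion_frac_max]
    dropped = set(alignment.species) - set(keep)
    if dropped:
        logger.info("filter_insertion_heavy %s: dropped %s",
                    alignment.gene_id, sorted(dropped))
    return alignment.subset(keep)


def filter_short_branch_genes(records: list[GeneSubstitutionRecord],
                              cfg: PipelineConfig | None = None,
                              ) -> list[GeneSubstitutionRecord]:
    """Drop records whose terminal branch length is strictly below
    ``gene_branch_min`` (high-variance dN/dS); the boundary is kept."""
    cfg = cfg or PipelineConfig()
    return [r for r in records if r.l >= cfg.gene_branch_min]


def apply_gene_blacklist(records: list[GeneSubstitutionRecord],
                         blacklist: set[str] | list[str],
                         ) -> list[GeneSubstitutionRecord]:
    """Remove blacklisted genes; unknown gene ids warn and no-op."""
    blk = set(blacklist)
    present = {r.gene_id for r in records}
    unknown = blk - present
    if unknown:
        logger.warning("blacklist entries not in dataset: %s", sorted(unknown))
    return [r for r in records if r.gene_id not in blk]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_species_dnds(records: list[GeneSubstitutionRecord],
                           denominator: str = "as_printed") -> SpeciesDnDs:
    """Aggregate one species' per-gene records into dN, dS and dN/dS.

    ``denominator='as_printed'`` divides sum(K) by sum(O/l);
    ``'counts_only'`` divides by sum(O).
    """
    if not records:
        raise ValueError("no records to aggregate")
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError(f"records span several species: {sorted(species)}")
    if denominator not in ("as_printed", "counts_only"):
        raise ValueError(f"unknown denominator {denominator!r}")
    kn = sum(r.K_N for r in records)
    ks = sum(r.K_S for r in records)
    if denominator == "as_printed":
        dn_den = sum(r.O_N / r.l for r in records)
        ds_den = sum(r.O_S / r.l for r in records)
    else:
        dn_den = sum(r.O_N for r in records)
        ds_den = sum(r.O_S for r in records)
    if dn_den == 0 or ds_den == 0:
        raise ZeroDivisionError("neutral-expectation denominator is zero")
    dn = kn / dn_den
    ds = ks / ds_den
    if ds == 0:
        raise ZeroDivisionError("dS is zero; dN/dS undefined")
    return SpeciesDnDs(species=species.pop(), dN=dn, dS=ds, dnds=dn / ds,
                       n_genes=len({r.gene_id for r in records}))


def aggregate_all_species(records: list[GeneSubstitutionRecord],
                          cfg: PipelineConfig | None = None,
                          blacklist: set[str] | None = None,
                          denominator: str = "as_printed") -> pd.DataFrame:
    """Filter then aggregate records for every species; species whose
    records are all filtered out are flagged and omitted."""
    cfg = cfg or PipelineConfig()
    records = filter_short_branch_genes(records, cfg)
    if blacklist:
        records = apply_gene_blacklist(records, blacklist)
    rows = []
    by_species: dict[str, list[GeneSubstitutionRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    for sp, recs in by_species.items():
        try:
            agg = aggregate_species_dnds(recs, denominator=denominator)
        except ZeroDivisionError:
            logger.warning("species %s: dN/dS undefined after aggregation", sp)
            continue
        rows.append({"species": sp, "dN": agg.dN, "dS": agg.dS,
                     "dnds": agg.dnds, "n_genes": agg.n_genes})
    return pd.DataFrame(rows).set_index("species") if rows else pd.DataFrame(
        columns=["dN", "dS", "dnds", "n_genes"])


# ---------------------------------------------------------------------------
# Terminal-branch trimming
# ---------------------------------------------------------------------------


def trim_terminal_branches(tree: Phylogeny, dnds_table: pd.DataFrame,
                           cfg: PipelineConfig | None = None,
                           ) -> tuple[Phylogeny, pd.DataFrame]:
    """Remove species whose terminal branch (amino-acid substitutions per
    site) is above ``terminal_branch_max`` or below ``terminal_branch_min``
    (both strict), prune the tree accordingly and subset the dN/dS table."""
    cfg = cfg or PipelineConfig()
    keep = [tip.name for tip in tree.tips()
            if cfg.terminal_branch_min <= tip.length <= cfg.terminal_branch_max]
    pruned = tree.prune_to(keep)
    reduced = dnds_table.loc[dnds_table.index.intersection(keep)]
    return pruned, reduced


# ---------------------------------------------------------------------------
# GC3 gene sets
# ---------------------------------------------------------------------------


def compute_gc3(alignment: CodonAlignment) -> float:
    """Fraction of G/C among ungapped third codon positions, pooled over
    species."""
    gc = total = 0
    for seq in alignment.sequences.values():
        third = seq[2::3]
        for ch in third:
            if ch == GAP:
                continue
            total += 1
            if ch in "GC":
                gc += 1
    if total == 0:
        raise ValueError(f"gene {alignment.gene_id}: no ungapped third "
                         "positions")
    return gc / total


def select_gc3_genesets(gc3: dict[str, float], coverage: dict[str, float],
                        cfg: PipelineConfig | None = None,
                        ) -> tuple[list[str], list[str]]:
    """(GC3-poorest, GC3-richest) gene sets of size ``gc3_set_size`` among
    genes covering at least ``gc3_coverage_min`` of the species; ties on
    GC3 break lexicographically by gene id."""
    cfg = cfg or PipelineConfig()
    eligible = sorted(g for g in gc3
                      if coverage.get(g, 0.0) >= cfg.gc3_coverage_min)
    ranked = sorted(eligible, key=lambda g: (gc3[g], g))
    k = cfg.gc3_set_size
    if len(ranked) < 2 * k:
        logger.warning("select_gc3_genesets: only %d eligible genes "
                       "(< 2 x %d); returning all in both sets",
                       len(ranked), k)
        return ranked, ranked
    return ranked[:k], ranked[-k:][::-1]
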