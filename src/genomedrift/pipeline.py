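"""End-to-end orchestration: simulate or load inputs, run every stage,
write stage TSVs and a reproducibility manifest.

Stage order follows the analysis: assembly QC filter -> genome-size
estimation -> per-gene codon fitting and substitution mapping -> per-species
dN/dS aggregation -> TE content summarization -> phylogenetically
controlled regressions.  All results go to files; logs go to stderr; runs
are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import comparative, dnds_aggregation, genome_size, te_landscape
from .codon_dnds import map_gene
from .core import (Phylogeny, PipelineConfig, SpeciesTraitTable,
                   filter_assemblies, logger, read_codon_fasta, read_newick,
                   read_trait_table, write_trait_table)
from .synthetic_data import ScenarioBundle, SimulationScenario, generate_scenario

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seed: int
    input_digests: dict[str, str]
    stage_rows: dict[str, int]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index_label: str | None = "species",
               ) -> None:
    df = df.sort_index()
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
              index_label=index_label)


# ---------------------------------------------------------------------------
# Input bundling
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    tree: Phylogeny
    traits: SpeciesTraitTable
    alignments: list
    te_annotations: dict[str, pd.DataFrame]
    cvalue_records: pd.DataFrame | None
    digests: dict[str, str]


def load_inputs(tree_path: str, traits_path: str, alignment_paths: list[str],
                te_dir: str | None = None,
                cvalue_path: str | None = None) -> PipelineInputs:
    """Read pipeline inputs from disk, recording file digests."""
    for path in [tree_path, traits_path, *alignment_paths]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input file not found: {path}")
    digests = {}
    with open(tree_path) as fh:
        tree = read_newick(fh.read())
    digests[tree_path] = _digest(tree_path)
    traits = read_trait_table(traits_path)
    digests[traits_path] = _digest(traits_path)
    alignments = []
    for p in alignment_paths:
        alignments.append(read_codon_fasta(p))
        digests[p] = _digest(p)
    te_annotations = {}
    if te_dir:
        for fname in sorted(os.listdir(te_dir)):
            if not fname.endswith(".tsv"):
                continue
            sp = fname[:-4]
            path = os.path.join(te_dir, fname)
            te_annotations[sp] = pd.read_csv(path, sep="\t")
            digests[path] = _digest(path)
    cvalue_records = None
    if cvalue_path:
        cvalue_records = pd.read_csv(cvalue_path, sep="\t")
        digests[cvalue_path] = _digest(cvalue_path)
    return PipelineInputs(tree=tree, traits=traits, alignments=alignments,
                          te_annotations=te_annotations,
                          cvalue_records=cvalue_records, digests=digests)


def inputs_from_bundle(bundle: ScenarioBundle) -> PipelineInputs:
    return PipelineInputs(tree=bundle.tree, traits=bundle.traits,
                          alignments=bundle.alignments,
                          te_annotations=bundle.te_annotations,
                          cvalue_records=bundle.cvalue_records,
                          digests={"simulated": f"seed={bundle.scenario.seed}"})


def write_bundle(bundle: ScenarioBundle, outdir: str) -> dict[str, str]:
    """Write a simulated bundle in the formats the readers consume."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    tree_path = os.path.join(outdir, "tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(bundle.tree.to_newick() + "\n")
    paths["tree"] = tree_path
    traits_path = os.path.join(outdir, "traits.tsv")
    write_trait_table(bundle.traits, traits_path)
    paths["traits"] = traits_path
    aln_dir = os.path.join(outdir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    from .core import write_codon_fasta

    for aln in bundle.alignments:
        p = os.path.join(aln_dir, f"{aln.gene_id}.fasta")
        write_codon_fasta(aln, p)
        paths[aln.gene_id] = p
    te_dir = os.path.join(outdir, "te_annotations")
    os.makedirs(te_dir, exist_ok=True)
    for sp, ann in bundle.te_annotations.items():
        p = os.path.join(te_dir, f"{sp}.tsv")
        ann.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
    paths["te_dir"] = te_dir
    cvalue_path = os.path.join(outdir, "cvalue_records.tsv")
    bundle.cvalue_records.to_csv(cvalue_path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    paths["cvalues"] = cvalue_path
    return paths


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(inputs: PipelineInputs, outdir: str,
                 cfg: PipelineConfig | None = None,
                 bootstrap_reps: int = 200,
                 max_genes: int | None = None) -> RunManifest:
    """Execute every stage and write stage outputs plus a manifest.

    ``max_genes`` caps the number of genes put through codon fitting (the
    most expensive stage); ``None`` uses all.
    """
    cfg = cfg or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_rows: dict[str, int] = {}

    # 1. assembly QC
    filtered = filter_assemblies(inputs.traits, cfg)
    stage_rows["filter_assemblies"] = len(filtered)
    path = os.path.join(outdir, "traits_filtered.tsv")
    _write_tsv(filtered.df, path)
    outputs["traits_filtered"] = path

    # 2. genome size
    sized = genome_size.estimate_genome_sizes(
        filtered, cvalue_records=inputs.cvalue_records, pg_to_bp=cfg.pg_to_bp)
    stage_rows["genome_size"] = len(sized)
    path = os.path.join(outdir, "genome_sizes.tsv")
    _write_tsv(sized.df[["assembly_size", "genome_size",
                         "genome_size_source"]], path)
    outputs["genome_sizes"] = path

    # 3. codon fitting + mapping
    genes = inputs.alignments[:max_genes] if max_genes else inputs.alignments
    records = []
    for aln in genes:
        aln = dnds_aggregation.filter_insertion_heavy(aln, cfg)
        recs, _, _ = map_gene(aln, inputs.tree, seed=cfg.seed)
        records.extend(recs)
    rec_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    stage_rows["substitution_records"] = len(rec_df)
    path = os.path.join(outdir, "substitution_records.tsv")
    rec_df.sort_values(["gene_id", "species"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    outputs["substitution_records"] = path

    # 4. per-species aggregation
    dnds = dnds_aggregation.aggregate_all_species(records, cfg)
    stage_rows["species_dnds"] = len(dnds)
    path = os.path.join(outdir, "species_dnds.tsv")
    _write_tsv(dnds, path)
    outputs["species_dnds"] = path

    # 5. TE content
    te = te_landscape.summarize_all_species(
        inputs.te_annotations, sized.df["genome_size"], cfg)
    stage_rows["te_content"] = len(te)
    path = os.path.join(outdir, "te_content.tsv")
    _write_tsv(te, path)
    outputs["te_content"] = path

    # 6. comparative analyses
    merged = sized.df.join(te, how="inner").join(dnds, how="inner")
    analyses = []
    tree = inputs.tree

    def pic_row(xcol: str, ycol: str, log_x: bool, log_y: bool) -> None:
        x = merged[xcol].astype(float)
        y = merged[ycol].astype(float)
        if log_x:
            x = np.log(x.where(x > 0))
        if log_y:
            y = np.log(y.where(y > 0))
        pair = pd.DataFrame({"x": x, "y": y}).dropna()
        if len(pair) < 4:
            logger.warning("PIC %s~%s skipped: too few species", ycol, xcol)
            return
        cx = comparative.compute_contrasts(tree, pair["x"])
        cy = comparative.compute_contrasts(tree, pair["y"])
        res = comparative.pic_regression(cx, cy)
        analyses.append({"x": xcol, "y": ycol, "method": "pic",
                         "slope": res.slope, "adj_r2": res.adj_r2,
                         "p_value": res.p_value, "n": res.n})

    def ols_row(xcol: str, ycol: str, log_x: bool, log_y: bool) -> None:
        pair = merged[[xcol, ycol]].dropna()
        if len(pair) < 4:
            return
        res = comparative.ols_regression(pair[xcol].to_numpy(),
                                         pair[ycol].to_numpy(),
                                         log_x=log_x, log_y=log_y)
        analyses.append({"x": xcol, "y": ycol, "method": "ols",
                         "slope": res.slope, "adj_r2": res.adj_r2,
                         "p_value": res.p_value, "n": res.n})

    if not merged.empty:
        ols_row("genome_size", "te_bp", True, True)
        pic_row("genome_size", "te_bp", True, True)
        pic_row("dnds", "te_bp", False, True)
        pic_row("dnds", "genome_size", False, True)
        pic_row("dnds", "recent_te_bp", False, True)

    reg_df = pd.DataFrame(analyses)
    stage_rows["regressions"] = len(reg_df)
    path = os.path.join(outdir, "regressions.tsv")
    reg_df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    outputs["regressions"] = path

    brownian_path = os.path.join(outdir, "brownian_fit.json")
    flagged_pairs = []
    cols = [c for c in ("dnds", "te_bp", "genome_size") if c in merged.columns]
    browse = merged[cols].copy()
    for c in ("te_bp", "genome_size"):
        if c in browse.columns:
            browse[c] = np.log(browse[c].where(browse[c] > 0))
    browse = browse.dropna()
    if len(browse) >= len(cols) + 2:
        fit = comparative.fit_brownian_multivariate(tree, browse)
        fit = comparative.bootstrap_support(tree, browse,
                                            n_reps=bootstrap_reps,
                                            seed=cfg.seed, fit=fit)
        flagged_pairs = [f"{a}~{b}" for (a, b), s in fit.support.items()
                         if s > 0.9 or s < 0.1]
        payload = {
            "traits": fit.trait_names,
            "R": fit.R.tolist(),
            "mu": fit.mu.tolist(),
            "correlation": fit.correlation.tolist(),
            "support": {f"{a}~{b}": s for (a, b), s in fit.support.items()},
            "flagged": flagged_pairs,
            "n": fit.n,
            "note": ("support from seeded parametric bootstrap; read like "
                     "posterior probabilities with the 0.1/0.9 convention"),
        }
        with open(brownian_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        outputs["brownian_fit"] = brownian_path

    # duplication screen rerun of the headline PIC
    _, reduced = comparative.duplication_screen(sized, cfg)
    stage_rows["duplication_reduced"] = len(reduced)

    manifest = RunManifest(
        config={k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                for k, v in dataclasses.asdict(cfg).items()},
        seed=cfg.seed, input_digests=inputs.digests,
        stage_rows=stage_rows, outputs=outputs)
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def run_simulated(scenario: SimulationScenario, outdir: str,
                  cfg: PipelineConfig | None = None,
                  bootstrap_reps: int = 200,
                  max_genes: int | None = None) -> RunManifest:
    """Generate a scenario and push it through the full pipeline."""
    bundle = generate_scenario(scenario)
    return run_pipeline(inputs_from_bundle(bundle), outdir, cfg=cfg,
                        bootstrap_reps=bootstrap_reps, max_genes=max_genes)


# ---------------------------------------------------------------------------
# Recomputation from deposited per-species tables
# ---------------------------------------------------------------------------


def reproduce_supplementary(tables: dict[str, str]) -> pd.DataFrame:
    """Recompute headline statistics from user-supplied per-species tables.

    ``tables`` maps dataset names to TSV paths with these schemas (header
    row, tab-separated; extra columns ignored):

    - ``cvalues``: species, assembly_size, cvalue_bp — assembly/C-value
      Pearson correlations (raw and log) and the WLS slope.
    - ``te_methods``: species, te_pct_assembly, te_pct_reads (and/or
      te_bp_assembly, te_bp_reads) — between-method Pearson correlations.
    - ``traits``: species, genome_size, te_bp [, recent_te_bp,
      busco_duplicated, dnds] — the log-log TE/genome-size OLS and the
      duplication regression.
    - ``dnds_variants``: species plus any two of dnds_full, dnds_trimmed,
      dnds_coevol_gc3poor, dnds_coevol_gc3rich — pairwise Pearson r.

    Returns a tidy report (dataset, statistic, value, n).
    """
    rows: list[dict] = []

    def add(dataset: str, statistic: str, value: float, n: int) -> None:
        rows.append({"dataset": dataset, "statistic": statistic,
                     "value": float(value), "n": int(n)})

    if "cvalues" in tables:
        df = pd.read_csv(tables["cvalues"], sep="\t")
        _need(df, "cvalues", ["assembly_size", "cvalue_bp"])
        df = df.dropna(subset=["assembly_size", "cvalue_bp"])
        stats = genome_size.assembly_cvalue_correlation(
            df["assembly_size"], df["cvalue_bp"])
        add("cvalues", "pearson_r_raw", stats["pearson_r_raw"], len(df))
        add("cvalues", "pearson_r_log", stats["pearson_r_log"], len(df))
        model = genome_size.fit_cvalue_wls(df["assembly_size"].to_numpy(),
                                           df["cvalue_bp"].to_numpy())
        add("cvalues", "wls_slope", model.slope, len(df))

    if "te_methods" in tables:
        df = pd.read_csv(tables["te_methods"], sep="\t")
        for a, b, name in [("te_pct_assembly", "te_pct_reads", "pearson_r_pct"),
                           ("te_bp_assembly", "te_bp_reads", "pearson_r_bp")]:
            if a in df.columns and b in df.columns:
                sub = df[[a, b]].dropna()
                r = np.corrcoef(sub[a], sub[b])[0, 1]
                add("te_methods", name, r, len(sub))

    if "traits" in tables:
        df = pd.read_csv(tables["traits"], sep="\t")
        _need(df, "traits", ["genome_size", "te_bp"])
        sub = df[["genome_size", "te_bp"]].dropna()
        res = comparative.ols_regression(sub["genome_size"], sub["te_bp"],
                                         log_x=True, log_y=True)
        add("traits", "loglog_slope_te_vs_genome_size", res.slope, res.n)
        add("traits", "loglog_adj_r2_te_vs_genome_size", res.adj_r2, res.n)
        if "busco_duplicated" in df.columns:
            sub = df[["busco_duplicated", "genome_size"]].dropna()
            res = comparative.ols_regression(sub["busco_duplicated"],
                                             sub["genome_size"])
            add("traits", "duplication_slope", res.slope, res.n)
            add("traits", "duplication_adj_r2", res.adj_r2, res.n)

    if "dnds_variants" in tables:
        df = pd.read_csv(tables["dnds_variants"], sep="\t")
        cols = [c for c in df.columns if c.startswith("dnds")]
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                sub = df[[cols[i], cols[j]]].dropna()
                if len(sub) >= 3:
                    r = np.corrcoef(sub[cols[i]], sub[cols[j]])[0, 1]
                    add("dnds_variants", f"pearson_r_{cols[i]}_{cols[j]}",
                        r, len(sub))

    if not rows:
        raise ValueError("no recognized dataset names given")
    return pd.DataFrame(rows)


def _need(df: pd.DataFrame, name: str, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"dataset {name!r} missing columns {missing}")
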