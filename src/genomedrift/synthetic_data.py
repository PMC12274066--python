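"""Generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analysis
assumes: quantitative traits diffusing along a phylogeny as a multivariate
Brownian motion; codon alignments evolving under YN98 with per-branch
omega optionally coupled to a latent (log effective population size) trait;
transposable-element copies whose divergence from their family consensus
reflects family age, observed through uniform low-coverage read sampling;
and C-value / assembly-size record pairs where the assembly underestimates
the genome progressively as genomes grow.

A scenario with a negative omega link is a world where the Mutational
Hazard Hypothesis holds by construction (low-Ne species have both elevated
dN/dS and more TEs); without the link, omega is flat and the hypothesis is
false by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_dnds import CodonModel
from .core import (CVALUE_METHODS, CodonAlignment, Phylogeny, PNode,
                   SpeciesTraitTable)
from .codon_dnds import CODONS, N_CODONS

# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------


@dataclass
class TEParams:
    """Repeat-landscape generator settings.

    Family ages are in expected substitutions per site on the copy/consensus
    divergence clock; read sampling emulates low-coverage annotation at the
    study's 0.25x genome coverage.
    """

    n_families: int = 12
    max_family_age: float = 0.35
    copies_per_family: int = 40
    copy_length: int = 2_000
    read_length: int = 150
    coverage: float = 0.25
    divergence_cap: float = 0.4
    divergence_sd: float = 0.01
    classes: tuple[str, ...] = ("DNA", "RC", "LTR", "LINE", "SINE",
                                "Other", "Unknown")

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        if self.max_family_age < 0 or self.copy_length <= 0:
            raise ValueError("invalid TE parameters")


@dataclass
class CValueError:
    """Noise model for C-value records: multiplicative lognormal error on
    the C-value and a size-dependent underestimation of the assembly,
    u(s) = u_max * s / (s + s_half), increasing in genome size."""

    sd: float = 0.05
    underestimation_max: float = 0.30
    # half-saturation sized to the default ~1e8-bp genome scale so the
    # underestimation is clearly visible across the simulated size range
    underestimation_halfsize: float = 2.0e8


@dataclass
class SimulationScenario:
    """Full description of a synthetic study.

    Traits diffuse with covariance ``R_true`` per unit branch length from
    root state ``mu``.  ``omega_link = (a, b)`` maps the first trait (the
    latent log-Ne) to per-branch omega = exp(a + b * trait), clipped to
    [0.01, 2]; ``None`` leaves omega constant at ``exp(a)`` of the default
    link intercept.
    """

    n_species: int = 100
    birth_rate: float = 1.0
    trait_names: tuple[str, ...] = ("log_ne", "log_te_bp", "log_genome_size",
                                    "log_body_mass")
    R_true: np.ndarray | None = None
    mu: np.ndarray | None = None
    omega_link: tuple[float, float] | None = (-1.0, -0.35)
    kappa: float = 2.0
    phi: np.ndarray | None = None
    n_genes: int = 20
    n_codons: int = 300
    te_params: TEParams = field(default_factory=TEParams)
    cvalue_error: CValueError = field(default_factory=CValueError)
    cvalue_fraction: float = 0.5
    sample_te_reads: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.trait_names)
        if self.R_true is None:
            # moderate rates; TE content and genome size strongly coupled,
            # both mildly negatively coupled to log-Ne (an MHH-like world)
            R = np.eye(p) * 0.5
            idx = {n: i for i, n in enumerate(self.trait_names)}
            if {"log_te_bp", "log_genome_size"} <= set(idx):
                i, j = idx["log_te_bp"], idx["log_genome_size"]
                R[i, j] = R[j, i] = 0.4
            if self.omega_link is not None and "log_ne" in idx:
                for other in ("log_te_bp", "log_genome_size"):
                    if other in idx:
                        i, j = idx["log_ne"], idx[other]
                        R[i, j] = R[j, i] = -0.25
            self.R_true = R
        self.R_true = np.asarray(self.R_true, dtype=float)
        if self.mu is None:
            # small-insect genome scale keeps read tables tractable while
            # preserving the study's 0.25x-coverage sampling structure
            defaults = {"log_ne": 0.0, "log_te_bp": np.log(2.5e7),
                        "log_genome_size": np.log(1.0e8),
                        "log_body_mass": np.log(500.0)}
            self.mu = np.array([defaults.get(n, 0.0) for n in self.trait_names])
        self.mu = np.asarray(self.mu, dtype=float)
        _check_psd(self.R_true)
        if self.R_true.shape != (p, p) or self.mu.shape != (p,):
            raise ValueError("R_true/mu dimensions inconsistent with traits")
        if self.phi is None:
            self.phi = np.full((3, 4), 0.25)


def _check_psd(R: np.ndarray) -> None:
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("covariance matrix not symmetric")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("covariance matrix not positive semi-definite")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, birth_rate: float = 1.0,
                  seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree on ``n_species`` tips, rescaled so the
    root-to-tip depth is one.

    Starting from two root lineages, waiting times between speciations are
    Exp(k * birth_rate); the tree is grown one extra waiting time past the
    last split so terminal branches are positive, then rescaled.  The tree
    is binary and ultrametric in time.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = PNode(name=None)
    a, b = PNode(parent=root), PNode(parent=root)
    root.children = [a, b]
    active: list[tuple[PNode, float]] = [(a, 0.0), (b, 0.0)]  # node, birth time
    now = 0.0
    while len(active) < n_species:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.length = now - born
        c1, c2 = PNode(parent=node), PNode(parent=node)
        node.children = [c1, c2]
        active.append((c1, now))
        active.append((c2, now))
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, (node, born) in enumerate(active):
        node.length = now - born
        node.name = f"sp{i + 1:04d}"
    tree = Phylogeny(root)
    depth = next(iter(tree.depths().values()))
    for node in tree.postorder():
        node.length /= depth
    return tree


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------


def simulate_brownian_traits(tree: Phylogeny, R: np.ndarray, mu: np.ndarray,
                             seed: int = 0,
                             trait_names: tuple[str, ...] | None = None,
                             ) -> pd.DataFrame:
    """Tip trait values under multivariate Brownian motion.

    Increments along a branch of length t are N(0, t * R), independent
    across branches.  Returns a species x trait DataFrame.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    _check_psd(R)
    p = len(mu)
    if R.shape != (p, p):
        raise ValueError("R and mu dimensions differ")
    rng = np.random.default_rng(seed)
    # eigen square root handles singular R (degenerate diffusion)
    w, v = np.linalg.eigh(R)
    root_half = v * np.sqrt(np.clip(w, 0.0, None))
    values: dict[int, np.ndarray] = {id(tree.root): mu.copy()}
    out = {}
    for node in tree.preorder():
        if node.parent is not None:
            step = root_half @ rng.standard_normal(p) * np.sqrt(node.length)
            values[id(node)] = values[id(node.parent)] + step
        if node.is_tip:
            out[node.name] = values[id(node)]
    df = pd.DataFrame.from_dict(out, orient="index",
                                columns=list(trait_names) if trait_names
                                else [f"trait{i}" for i in range(p)])
    df.index.name = "species"
    return df


def branch_midpoint_traits(tree: Phylogeny, R: np.ndarray, mu: np.ndarray,
                           seed: int = 0) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tip traits plus, for each terminal branch, the trait value at the
    branch's parent-side endpoint averaged with the tip value — the latent
    value that drives the branch's omega."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    _check_psd(R)
    p = len(mu)
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(R)
    root_half = v * np.sqrt(np.clip(w, 0.0, None))
    values: dict[int, np.ndarray] = {id(tree.root): mu.copy()}
    tips = {}
    mids = {}
    for node in tree.preorder():
        if node.parent is not None:
            step = root_half @ rng.standard_normal(p) * np.sqrt(node.length)
            values[id(node)] = values[id(node.parent)] + step
        if node.is_tip:
            tips[node.name] = values[id(node)]
            mids[node.name] = float(
                0.5 * (values[id(node)][0] + values[id(node.parent)][0]))
    df = pd.DataFrame.from_dict(tips, orient="index")
    df.index.name = "species"
    return df, mids


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------


def simulate_codon_alignment(tree: Phylogeny, model: CodonModel,
                             n_codons: int,
                             branch_omegas: dict[str, float] | float | None = None,
                             seed: int = 0,
                             gene_id: str = "gene") -> CodonAlignment:
    """Evolve ``n_codons`` codons along the tree under YN98.

    ``branch_omegas`` maps tip names to per-terminal-branch omega (internal
    branches keep the model's omega), or is a single constant, or ``None``
    to use the model's omega everywhere.  The root sequence is drawn from
    the model's stationary distribution; the output is gap-free.
    """
    rng = np.random.default_rng(seed)
    root_states = rng.choice(N_CODONS, size=n_codons, p=model.pi)
    model_cache: dict[float, CodonModel] = {model.omega: model}

    def model_for(omega: float) -> CodonModel:
        if omega not in model_cache:
            model_cache[omega] = CodonModel(model.kappa, omega, model.phi)
        return model_cache[omega]

    def branch_omega(node: PNode) -> float:
        if branch_omegas is None:
            return model.omega
        if isinstance(branch_omegas, dict):
            if node.is_tip and node.name in branch_omegas:
                return float(branch_omegas[node.name])
            return model.omega
        return float(branch_omegas)

    seqs: dict[str, str] = {}
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        if node.parent is not None:
            omega = branch_omega(node)
            if omega < 0:
                raise ValueError("branch omega must be non-negative")
            P = model_for(omega).transition_matrix(node.length)
            parent = states[id(node.parent)]
            cum = P.cumsum(axis=1)
            u = rng.random(len(parent))
            child = (u[:, None] > cum[parent]).sum(axis=1)
            states[id(node)] = child.astype(np.int64)
        if node.is_tip:
            seqs[node.name] = "".join(CODONS[s] for s in states[id(node)])
    return CodonAlignment(gene_id, seqs)


# ---------------------------------------------------------------------------
# TE landscape simulation
# ---------------------------------------------------------------------------


def simulate_te_genome(te_params: TEParams, genome_size: float, seed: int = 0,
                       te_bp_target: float | None = None,
                       rate_multiplier: float = 1.0,
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """One species' read-level repeat annotations plus the true totals.

    Families get ages uniform on [0, max_family_age]; a copy's divergence
    from its family consensus is Jukes-Cantor-like saturating,
    d = cap * (1 - exp(-age / cap)), plus small per-copy noise.  Reads of
    fixed length are placed uniformly over the genome at the configured
    coverage; a read landing in a TE copy is annotated with the copy's
    family class and divergence over its full length, otherwise it carries
    no annotation.  Returns the annotation table and
    {"true_te_bp", "true_recent_te_bp"} (recent: divergence < 0.05).
    """
    p = te_params
    rng = np.random.default_rng(seed)
    n_reads = max(int(round(p.coverage * genome_size / p.read_length)), 1)
    if p.n_families == 0:
        table = pd.DataFrame({
            "read_id": np.arange(n_reads),
            "read_bp": np.full(n_reads, p.read_length, dtype=np.int32),
            "annotated_bp": np.zeros(n_reads, dtype=np.int32),
            "repeat_class": pd.Categorical.from_codes(
                np.zeros(n_reads, dtype=np.int8), categories=["none"]),
            "divergence": np.full(n_reads, np.nan),
        })
        return table, {"true_te_bp": 0.0, "true_recent_te_bp": 0.0}

    ages = rng.uniform(0.0, p.max_family_age, size=p.n_families) * rate_multiplier
    classes = [p.classes[i % len(p.classes)] for i in range(p.n_families)]
    copies = np.full(p.n_families, p.copies_per_family, dtype=float)
    if te_bp_target is not None:
        raw = copies * p.copy_length
        copies = np.maximum(
            np.round(copies * te_bp_target / raw.sum()), 1.0)
    copy_div = []
    copy_class = []
    for fam in range(p.n_families):
        expected = p.divergence_cap * (1.0 - np.exp(-ages[fam] / p.divergence_cap))
        d = rng.normal(expected, p.divergence_sd, size=int(copies[fam]))
        copy_div.append(np.clip(d, 0.0, p.divergence_cap))
        copy_class.extend([classes[fam]] * int(copies[fam]))
    copy_div = np.concatenate(copy_div)
    copy_class = np.array(copy_class)
    n_copies = len(copy_div)
    te_bp = float(n_copies * p.copy_length)
    if te_bp > genome_size:
        raise ValueError("TE space exceeds genome size")
    recent_bp = float((copy_div < 0.05).sum() * p.copy_length)

    # uniform placement: P(read in TE space) = te_bp / genome_size
    in_te = rng.random(n_reads) < te_bp / genome_size
    copy_idx = rng.integers(0, n_copies, size=n_reads)
    categories = ["none"] + list(dict.fromkeys(copy_class))
    cls_code = {c: k for k, c in enumerate(categories)}
    class_codes = np.array([cls_code[c] for c in copy_class], dtype=np.int8)
    codes = np.where(in_te, class_codes[copy_idx], 0).astype(np.int8)
    table = pd.DataFrame({
        "read_id": np.arange(n_reads),
        "read_bp": np.full(n_reads, p.read_length, dtype=np.int32),
        "annotated_bp": np.where(in_te, p.read_length, 0).astype(np.int32),
        "repeat_class": pd.Categorical.from_codes(codes,
                                                  categories=categories),
        "divergence": np.where(in_te, copy_div[copy_idx], np.nan),
    })
    return table, {"true_te_bp": te_bp, "true_recent_te_bp": recent_bp}


# ---------------------------------------------------------------------------
# C-value records
# ---------------------------------------------------------------------------


def simulate_cvalue_records(true_sizes: np.ndarray,
                            cvalue_error: CValueError | None = None,
                            seed: int = 0,
                            species: list[str] | None = None,
                            pg_to_bp: float = 0.978e9) -> pd.DataFrame:
    """C-value / assembly-size record pairs with heteroscedastic structure.

    cvalue_bp = true_size * lognormal(0, sd); assembly_size = true_size *
    (1 - u(true_size)) with u increasing in size, so assemblies
    underestimate large genomes more.  Methods and dates cycle
    deterministically.
    """
    err = cvalue_error or CValueError()
    sizes = np.asarray(true_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("true sizes must be positive")
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, err.sd, size=len(sizes)))
    cvalue_bp = sizes * noise
    under = err.underestimation_max * sizes / (sizes + err.underestimation_halfsize)
    assembly = sizes * (1.0 - under)
    names = species or [f"sp{i + 1:04d}" for i in range(len(sizes))]
    return pd.DataFrame({
        "species": names,
        "assembly_size": assembly,
        "cvalue": cvalue_bp / pg_to_bp,
        "cvalue_method": [CVALUE_METHODS[i % 3] for i in range(len(sizes))],
        "cvalue_date": [2000 + (i % 23) for i in range(len(sizes))],
        "true_size": sizes,
    })


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    """Mutually consistent synthetic inputs for a full pipeline run."""

    scenario: SimulationScenario
    tree: Phylogeny
    traits: SpeciesTraitTable
    alignments: list[CodonAlignment]
    te_annotations: dict[str, pd.DataFrame]
    te_truth: pd.DataFrame
    cvalue_records: pd.DataFrame
    branch_omegas: dict[str, float]


def generate_scenario(scenario: SimulationScenario) -> ScenarioBundle:
    """Generate the full input bundle for one scenario.

    The latent first trait (log-Ne) drives per-terminal-branch omega through
    the omega link when set; TE content and genome size are exponentiated
    Brownian traits; C-value records and read-level TE annotations are
    derived from the same per-species true sizes, so every output shares
    one species set.
    """
    sc = scenario
    master = np.random.default_rng(sc.seed)
    seeds = master.integers(0, 2**31 - 1, size=6)
    tree = simulate_tree(sc.n_species, sc.birth_rate, seed=int(seeds[0]))
    traits_df, mid_latent = branch_midpoint_traits(
        tree, sc.R_true, sc.mu, seed=int(seeds[1]))
    traits_df.columns = list(sc.trait_names)

    if sc.omega_link is not None:
        a, b = sc.omega_link
        branch_omegas = {sp: float(np.clip(np.exp(a + b * mid_latent[sp]),
                                           0.01, 2.0))
                         for sp in tree.tip_names}
    else:
        branch_omegas = {sp: float(np.exp(-1.0)) for sp in tree.tip_names}

    model = CodonModel(sc.kappa, 0.2, sc.phi)
    alignments = []
    for g in range(sc.n_genes):
        alignments.append(simulate_codon_alignment(
            tree, model, sc.n_codons, branch_omegas=branch_omegas,
            seed=int(seeds[2]) + g, gene_id=f"gene{g + 1:04d}"))

    idx = {n: i for i, n in enumerate(sc.trait_names)}
    genome_size = np.exp(traits_df["log_genome_size"]).to_numpy() \
        if "log_genome_size" in idx else np.full(len(traits_df), 1.0e8)
    te_target = np.exp(traits_df["log_te_bp"]).to_numpy() \
        if "log_te_bp" in idx else np.full(len(traits_df), 2.5e7)
    te_target = np.minimum(te_target, 0.8 * genome_size)

    te_annotations = {}
    te_truth_rows = []
    species = traits_df.index.tolist()
    for k, sp in enumerate(species):
        if sc.sample_te_reads:
            ann, truth = simulate_te_genome(
                sc.te_params, genome_size[k], seed=int(seeds[3]) + k,
                te_bp_target=float(te_target[k]))
            te_annotations[sp] = ann
        else:  # trait-level world only; skip the read-sampling stage
            truth = {"true_te_bp": float(te_target[k]),
                     "true_recent_te_bp": np.nan}
        te_truth_rows.append({"species": sp, **truth})
    te_truth = pd.DataFrame(te_truth_rows).set_index("species")

    records = simulate_cvalue_records(
        genome_size, sc.cvalue_error, seed=int(seeds[4]), species=species)
    # only a fraction of species keep a C-value record, as in real data
    rng = np.random.default_rng(int(seeds[5]))
    has_cvalue = rng.random(len(species)) < sc.cvalue_fraction

    df = pd.DataFrame(index=pd.Index(species, name="species"))
    df["assembly_size"] = records.set_index("species")["assembly_size"]
    df["cvalue"] = np.where(has_cvalue,
                            records.set_index("species")["cvalue"], np.nan)
    df["cvalue_method"] = records.set_index("species")["cvalue_method"]
    df["cvalue_date"] = records.set_index("species")["cvalue_date"]
    df["contig_n50"] = 1.0e6
    df["busco_complete"] = 95.0
    df["busco_duplicated"] = 5.0
    df["true_genome_size"] = genome_size
    df["true_te_bp"] = te_truth["true_te_bp"]
    df["true_recent_te_bp"] = te_truth["true_recent_te_bp"]
    df["true_dnds"] = pd.Series(branch_omegas)
    for name in sc.trait_names:
        df[name] = traits_df[name]

    bundle = ScenarioBundle(
        scenario=sc, tree=tree, traits=SpeciesTraitTable(df),
        alignments=alignments, te_annotations=te_annotations,
        te_truth=te_truth,
        cvalue_records=records[has_cvalue] if has_cvalue.any()
        else records.iloc[:0],
        branch_omegas=branch_omegas)
    _check_bundle(bundle)
    return bundle


def _check_bundle(bundle: ScenarioBundle) -> None:
    species = set(bundle.tree.tip_names)
    if set(bundle.traits.species) != species:
        raise ValueError("species sets inconsistent between tree and traits")
    for aln in bundle.alignments:
        if set(aln.species) != species:
            raise ValueError(f"species set of {aln.gene_id} inconsistent")
    if bundle.te_annotations and set(bundle.te_annotations) != species:
        raise ValueError("species sets inconsistent for TE annotations")
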