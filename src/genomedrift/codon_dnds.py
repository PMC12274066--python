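"""YN98(F3X4) codon model: likelihood, ML fitting and substitution mapping.

The model is the Yang & Nielsen (1998) codon substitution process on the 61
sense codons of the universal genetic code.  Off-diagonal rates between
codons differing at exactly one position are

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero between codons differing at more than one position, and the matrix is
rescaled so the expected number of substitutions per unit branch length is
one.  Codon frequencies pi follow the F3X4 parameterization (products of
position-specific nucleotide frequencies, renormalized over sense codons).

Per-branch dN/dS is obtained by substitution mapping: the posterior expected
number of nonsynonymous (K_N) and synonymous (K_S) substitutions on a branch
given the alignment, against the unconditional expectations (O_N, O_S) under
the same model with omega reset to 1.  Labeled-jump expectations are
computed analytically from the spectral decomposition of Q, which is real
because the chain is reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import minimize

from .core import GAP, NUCLEOTIDES, CodonAlignment, Phylogeny, PNode, logger

# ---------------------------------------------------------------------------
# Genetic code tables
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c
           for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
           if a + b + c not in _TABLE.stop_codons))
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACID = {c: _TABLE.forward_table[c] for c in CODONS}
MISSING = N_CODONS  # sentinel state for gapped/ambiguous codons

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pair_tables():
    """Boolean 61x61 masks: single-step, transition, nonsynonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = _is_transition(a, b)
            nonsyn[i, j] = AMINO_ACID[ci] != AMINO_ACID[cj]
    return single, transition, nonsyn


SINGLE_STEP, TRANSITION, NONSYNONYMOUS = _pair_tables()
SYNONYMOUS = SINGLE_STEP & ~NONSYNONYMOUS


# ---------------------------------------------------------------------------
# F3X4 frequencies and the rate matrix
# ---------------------------------------------------------------------------


def build_f3x4(phi: np.ndarray) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    ``phi`` is a 3x4 row-stochastic matrix (rows: codon positions, columns
    in ``ACGT`` order).  Returns the length-61 stationary distribution with
    stop codons excluded and the rest renormalized.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (3, 4):
        raise ValueError("phi must be 3x4")
    if np.any(phi < 0) or not np.allclose(phi.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("phi rows must be non-negative and sum to 1")
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array([
        phi[0, nt_index[c[0]]] * phi[1, nt_index[c[1]]] * phi[2, nt_index[c[2]]]
        for c in CODONS])
    total = pi.sum()
    if total <= 0:
        raise ValueError("phi assigns zero mass to every sense codon")
    return pi / total


def observed_phi(alignment: CodonAlignment) -> np.ndarray:
    """Position-specific nucleotide frequencies from an alignment, gaps
    excluded; falls back to uniform rows when a position is all-gap."""
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in alignment.sequences.values():
        for pos in range(3):
            for ch in seq[pos::3]:
                if ch != GAP:
                    counts[pos, nt_index[ch]] += 1
    for pos in range(3):
        if counts[pos].sum() == 0:
            counts[pos] = 1.0
    # guard against zero cells that would null out whole codon classes
    counts += 0.5
    return counts / counts.sum(axis=1, keepdims=True)


def build_yn98_rate_matrix(kappa: float, omega: float,
                           pi: np.ndarray) -> np.ndarray:
    """YN98 rate matrix scaled to mean rate one (61x61)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must be a distribution over the 61 sense codons")
    Q = np.where(SINGLE_STEP, np.tile(pi, (N_CODONS, 1)), 0.0)
    Q = Q * np.where(TRANSITION, kappa, 1.0) * np.where(NONSYNONYMOUS, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (mean rate 0)")
    return Q / mean_rate


@dataclass
class CodonModel:
    """Fitted (or assumed) YN98(F3X4) model.

    Holds kappa, omega, the positional frequencies phi, the derived codon
    frequencies pi and scaled rate matrix Q, plus the spectral decomposition
    used for transition probabilities and labeled-jump integrals.
    """

    kappa: float
    omega: float
    phi: np.ndarray
    pi: np.ndarray = field(init=False)
    Q: np.ndarray = field(init=False)
    converged: bool = True
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.pi = build_f3x4(self.phi)
        self.Q = build_yn98_rate_matrix(self.kappa, self.omega, self.pi)
        # reversible chain: symmetrize with sqrt(pi) and use a real
        # eigendecomposition
        d = np.sqrt(self.pi)
        sym = (d[:, None] * self.Q) / d[None, :]
        w, v = np.linalg.eigh(0.5 * (sym + sym.T))
        self._eigval = w
        self._U = v / d[:, None]
        self._Uinv = v.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._U * np.exp(self._eigval * t)) @ self._Uinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def labeled_integral(self, t: float, labeled: np.ndarray) -> np.ndarray:
        """I_L(t)[i, j] = E[#labeled jumps in (0, t); X(t)=j | X(0)=i].

        Computed from the spectral decomposition: with Q = U diag(w) U^-1,
        I_L = U ((U^-1 Q_L U) * J) U^-1 where J_kl integrates
        exp(w_k s) exp(w_l (t-s)) over s in (0, t).  Coincident eigenvalues
        use the analytic limit t*exp(w t).
        """
        QL = np.where(labeled, self.Q, 0.0)
        w = self._eigval
        ew = np.exp(w * t)
        diff = w[:, None] - w[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            J = (ew[:, None] - ew[None, :]) / diff
        close = np.abs(diff) < 1e-12
        J[close] = (t * ew[:, None] * np.ones_like(J))[close]
        M = self._Uinv @ QL @ self._U
        I = self._U @ (M * J) @ self._Uinv
        np.clip(I, 0.0, None, out=I)
        return I

    def label_rates(self) -> tuple[float, float]:
        """Stationary flux into nonsynonymous / synonymous changes
        (fractions of the unit mean rate)."""
        rho_n = float(self.pi @ np.where(NONSYNONYMOUS, self.Q, 0.0).sum(axis=1))
        rho_s = float(self.pi @ np.where(SYNONYMOUS, self.Q, 0.0).sum(axis=1))
        return rho_n, rho_s


@dataclass
class GeneSubstitutionRecord:
    """Mapped and neutral substitution counts for one gene on one terminal
    branch; the unit aggregated into per-species dN/dS."""

    gene_id: str
    species: str
    K_N: float
    K_S: float
    O_N: float
    O_S: float
    l: float

    def __post_init__(self) -> None:
        for name in ("K_N", "K_S", "O_N", "O_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.l <= 0:
            raise ValueError("branch length l must be > 0")


# ---------------------------------------------------------------------------
# Pattern compression and pruning likelihood
# ---------------------------------------------------------------------------


def _encode_alignment(alignment: CodonAlignment,
                      tip_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Codon-state matrix (tips x patterns) and pattern multiplicities.

    Codons containing a gap (or ambiguity, mapped to gaps at read time) get
    the MISSING state.  An in-frame stop codon in the data is a hard error.
    """
    n = alignment.n_codons
    states = np.empty((len(tip_names), n), dtype=np.int16)
    for row, name in enumerate(tip_names):
        try:
            seq = alignment.sequences[name]
        except KeyError:
            raise KeyError(f"tree tip {name!r} has no sequence in gene "
                           f"{alignment.gene_id!r}") from None
        for k in range(n):
            codon = seq[3 * k : 3 * k + 3]
            if GAP in codon:
                states[row, k] = MISSING
            elif codon in CODON_INDEX:
                states[row, k] = CODON_INDEX[codon]
            else:
                raise ValueError(
                    f"in-frame stop codon {codon} in {name!r}, gene "
                    f"{alignment.gene_id!r}, codon {k}")
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class TreeLikelihood:
    """Felsenstein pruning machinery for one (alignment, tree, model).

    Keeps per-node conditional ("up") partials with log-scaling, the
    site-pattern log-likelihoods, and lazily computes the outside partials
    needed for branch-wise substitution mapping.
    """

    def __init__(self, alignment: CodonAlignment, tree: Phylogeny,
                 model: CodonModel):
        self.alignment = alignment
        self.tree = tree
        self.model = model
        self.nodes = list(tree.postorder())
        self.node_id = {id(n): k for k, n in enumerate(self.nodes)}
        tipnames = tree.tip_names
        self.patterns, self.counts = _encode_alignment(alignment, tipnames)
        self.tip_row = {name: r for r, name in enumerate(tipnames)}
        self.n_pat = self.patterns.shape[1]
        self._edge_P: dict[int, np.ndarray] = {}
        self._run_up()

    def _P(self, node: PNode) -> np.ndarray:
        key = self.node_id[id(node)]
        if key not in self._edge_P:
            self._edge_P[key] = self.model.transition_matrix(node.length)
        return self._edge_P[key]

    def _run_up(self) -> None:
        npat = self.n_pat
        self.up: list[np.ndarray] = [None] * len(self.nodes)
        self.up_scale: list[np.ndarray] = [None] * len(self.nodes)
        for k, node in enumerate(self.nodes):
            if node.is_tip:
                states = self.patterns[self.tip_row[node.name]]
                part = np.zeros((npat, N_CODONS))
                obs = states < MISSING
                part[obs, states[obs]] = 1.0
                part[~obs, :] = 1.0
                self.up[k] = part
                self.up_scale[k] = np.zeros(npat)
            else:
                part = np.ones((npat, N_CODONS))
                scale = np.zeros(npat)
                for child in node.children:
                    ck = self.node_id[id(child)]
                    part = part * (self.up[ck] @ self._P(child).T)
                    scale = scale + self.up_scale[ck]
                m = part.max(axis=1)
                m[m == 0] = 1.0
                self.up[k] = part / m[:, None]
                self.up_scale[k] = scale + np.log(m)
        rk = self.node_id[id(self.tree.root)]
        site = self.up[rk] @ self.model.pi
        self.pattern_loglik = np.log(site) + self.up_scale[rk]

    @property
    def log_likelihood(self) -> float:
        return float(self.counts @ self.pattern_loglik)

    # -- outside pass -------------------------------------------------------

    def _run_outside(self) -> None:
        if hasattr(self, "pre"):
            return
        npat = self.n_pat
        # pre[v] = likelihood of data outside v's subtree, indexed by the
        # state at v's *parent* (before crossing the edge into v)
        self.pre: list[np.ndarray] = [None] * len(self.nodes)
        self.pre_scale: list[np.ndarray] = [None] * len(self.nodes)
        rk = self.node_id[id(self.tree.root)]
        out_root = np.tile(self.model.pi, (npat, 1))
        scales = {rk: np.zeros(npat)}
        outs = {rk: out_root}
        for node in self.tree.preorder():
            nk = self.node_id[id(node)]
            out_n, sc_n = outs[nk], scales[nk]
            for child in node.children:
                ck = self.node_id[id(child)]
                pre = out_n.copy()
                sc = sc_n.copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    sk = self.node_id[id(sib)]
                    pre = pre * (self.up[sk] @ self._P(sib).T)
                    sc = sc + self.up_scale[sk]
                self.pre[ck] = pre
                self.pre_scale[ck] = sc
                out_c = pre @ self._P(child)
                m = out_c.max(axis=1)
                m[m == 0] = 1.0
                outs[ck] = out_c / m[:, None]
                scales[ck] = sc + np.log(m)

    def branch_expected_counts(self, node: PNode,
                               labeled: np.ndarray) -> float:
        """Posterior expected labeled jumps on the branch above ``node``,
        summed over sites."""
        if node.parent is None:
            raise ValueError("the root has no branch")
        self._run_outside()
        nk = self.node_id[id(node)]
        I = self.model.labeled_integral(node.length, labeled)
        pre, upv = self.pre[nk], self.up[nk]
        per_pat = np.einsum("pi,ij,pj->p", pre, I, upv)
        logw = self.pre_scale[nk] + self.up_scale[nk] - self.pattern_loglik
        return float(self.counts @ (per_pat * np.exp(logw)))


def log_likelihood(alignment: CodonAlignment, tree: Phylogeny,
                   model: CodonModel) -> float:
    """Pruning-algorithm log-likelihood; gapped codons are missing data."""
    return TreeLikelihood(alignment, tree, model).log_likelihood


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

KAPPA_BOUNDS = (0.05, 100.0)
OMEGA_BOUNDS = (1e-4, 10.0)
BL_BOUNDS = (1e-7, 20.0)


def fit_yn98(alignment: CodonAlignment, tree: Phylogeny,
             branch_mode: str = "fixed",
             n_restarts: int = 3, seed: int = 0,
             ) -> tuple[CodonModel, Phylogeny]:
    """Fit kappa and omega by bounded quasi-Newton from multiple starts;
    F3X4 frequencies are fixed at the observed positional counts.

    ``branch_mode`` controls branch-length handling: ``'fixed'`` keeps the
    input lengths, ``'scaled'`` co-estimates one gene-wide rate multiplier
    on the input lengths, ``'free'`` re-estimates every branch length
    (accurate but costly on large trees).  Returns the fitted model (with
    ``log_likelihood`` and ``converged`` set) and the tree actually used.
    """
    if branch_mode not in ("fixed", "scaled", "free"):
        raise ValueError(f"unknown branch_mode {branch_mode!r}")
    phi = observed_phi(alignment)
    work = tree.copy()
    edges = [n for n in work.postorder() if n.parent is not None]
    rng = np.random.default_rng(seed)

    base_bl = np.array([max(n.length, 1e-6) for n in edges])

    def unpack(x):
        kappa = float(np.exp(x[0]))
        omega = float(np.exp(x[1]))
        if branch_mode == "scaled":
            mult = float(np.exp(x[2]))
            for node, b in zip(edges, base_bl):
                node.length = b * mult
        elif branch_mode == "free":
            for node, lb in zip(edges, x[2:]):
                node.length = float(np.exp(lb))
        return kappa, omega

    def objective(x):
        kappa, omega = unpack(x)
        model = CodonModel(kappa, omega, phi)
        return -log_likelihood(alignment, work, model)

    bounds = [tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(OMEGA_BOUNDS))]
    if branch_mode == "scaled":
        bounds += [(np.log(1e-3), np.log(1e3))]
    elif branch_mode == "free":
        bounds += [tuple(np.log(BL_BOUNDS))] * len(edges)

    starts = [np.array([np.log(2.0), np.log(0.5)])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.array([
            rng.uniform(np.log(0.5), np.log(8.0)),
            rng.uniform(np.log(0.05), np.log(2.0))]))
    if branch_mode == "scaled":
        starts = [np.concatenate([s, [0.0]]) for s in starts]
    elif branch_mode == "free":
        starts = [np.concatenate([s, np.log(base_bl)]) for s in starts]

    best = None
    ok = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    if not ok:
        logger.warning("fit_yn98: optimizer did not converge for gene %s; "
                       "best point returned", alignment.gene_id)
    kappa, omega = unpack(best.x)
    model = CodonModel(kappa, omega, phi)
    model.converged = ok
    model.log_likelihood = -float(best.fun)
    return model, work


# ---------------------------------------------------------------------------
# Substitution mapping
# ---------------------------------------------------------------------------


def expected_labeled_counts(model: CodonModel, tree: Phylogeny,
                            alignment: CodonAlignment,
                            branch: str | PNode) -> tuple[float, float]:
    """Posterior expected (K_N, K_S) on one branch given the data.

    ``branch`` is a tip name or a node of ``tree``; the branch is the edge
    above that node.
    """
    node = tree.find_tip(branch) if isinstance(branch, str) else branch
    tl = TreeLikelihood(alignment, tree, model)
    return (tl.branch_expected_counts(node, NONSYNONYMOUS),
            tl.branch_expected_counts(node, SYNONYMOUS))


def neutral_expected_counts(model: CodonModel, branch_length: float,
                            n_sites: int) -> tuple[float, float]:
    """Unconditional (O_N, O_S) on a branch of length ``branch_length``
    under the fitted model with omega reset to 1 (kappa and pi retained,
    matrix rescaled to unit mean rate); O_N + O_S = l * n_sites exactly."""
    neutral = CodonModel(model.kappa, 1.0, model.phi)
    rho_n, rho_s = neutral.label_rates()
    return (branch_length * n_sites * rho_n, branch_length * n_sites * rho_s)


def map_gene(alignment: CodonAlignment, tree: Phylogeny,
             branch_mode: str = "scaled", seed: int = 0,
             n_restarts: int = 3,
             ) -> tuple[list[GeneSubstitutionRecord], CodonModel, Phylogeny]:
    """Fit the model for one gene and map every terminal branch.

    The tree is pruned to the species present in the alignment; by default
    a gene-wide rate multiplier on the species-tree branch lengths is
    co-estimated (``branch_mode='scaled'``), so per-gene terminal branch
    lengths l(i) reflect the gene's own rate.  Returns the per-species
    substitution records together with the fitted model and tree.
    """
    common = [s for s in tree.tip_names if s in alignment.sequences]
    if len(common) < 2:
        raise ValueError(f"gene {alignment.gene_id}: fewer than 2 species "
                         "shared with the tree")
    sub_tree = tree.prune_to(common) if len(common) < tree.n_tips else tree
    sub_aln = alignment.subset(common)
    model, fitted = fit_yn98(sub_aln, sub_tree, branch_mode=branch_mode,
                             n_restarts=n_restarts, seed=seed)
    tl = TreeLikelihood(sub_aln, fitted, model)
    records = []
    n_sites = sub_aln.n_codons
    for tip in fitted.tips():
        if tip.length <= 0:
            logger.warning("map_gene %s: zero-length terminal branch %s "
                           "skipped", alignment.gene_id, tip.name)
            continue
        kn = tl.branch_expected_counts(tip, NONSYNONYMOUS)
        ks = tl.branch_expected_counts(tip, SYNONYMOUS)
        on, os_ = neutral_expected_counts(model, tip.length, n_sites)
        records.append(GeneSubstitutionRecord(
            gene_id=alignment.gene_id, species=tip.name,
            K_N=max(kn, 0.0), K_S=max(ks, 0.0), O_N=on, O_S=os_,
            l=tip.length))
    return records, model, fitted
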