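"""Assembly core: max-K-cut SDP relaxation, rounding and consensus.

Fragments of one strongly connected component are clustered into the K
haplotypes of a K-ploid organism.  Pairwise agreement is summarized by

    W_ij = (#mismatched alleles - #matched alleles) / #shared SNPs,

so W_ij = -1 for fully agreeing pairs and +1 for fully conflicting ones
(pairs sharing no SNP contribute nothing).  Clustering is the max-K-cut
semidefinite relaxation

    minimize  Tr(W X)
    s.t.      X_ii = 1,  X_ij >= -1/(K-1),  X PSD,

whose optimum is rounded to cluster labels by drawing K standard-normal
vectors and assigning fragment i to the cluster whose vector has maximal
inner product with column i of X (repeated over restarts, keeping the
assignment with the best score).  Each cluster is finally collapsed into a
haplotype by per-site majority voting.

The SDP is solved by an augmented-Lagrangian method on the dual: the
multiplier matrix Y is updated with step sigma = mu while the inner
subproblem over the box multipliers and the PSD dual matrix Z is solved by
alternating closed-form projections (box projection and an
eigendecomposition-based projection onto the PSD cone).  Iteration stops
when the relative duality gap (with a dual objective certified by an
explicitly feasible dual point) falls below ``gap_tol`` and the primal
feasibility residual is below ~1e-6.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragio import Fragment

logger = logging.getLogger(__name__)

GAP = -1  # allele code for an uncovered haplotype position
_N_ALLELES = 4


class SolverConvergenceError(RuntimeError):
    def __init__(self, msg: str, gap: float):
        super().__init__(msg)
        self.gap = gap


# ---------------------------------------------------------------------------
# Conflict weights


def fragment_arrays(
    fragments: Sequence[Fragment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, int]]:
    """Flatten fragment calls into (fragment row, site column, allele).

    Site columns are 0-based over the sorted union of covered variant
    indices; the returned map sends variant index -> column.
    """
    sites = sorted({c.variant_index for f in fragments for c in f.calls})
    col = {s: j for j, s in enumerate(sites)}
    fi, si, al = [], [], []
    for i, frag in enumerate(fragments):
        for c in frag.calls:
            fi.append(i)
            si.append(col[c.variant_index])
            al.append(c.allele)
    return (
        np.asarray(fi, dtype=np.int64),
        np.asarray(si, dtype=np.int64),
        np.asarray(al, dtype=np.int64),
        col,
    )


def build_conflict_weights(fragments: Sequence[Fragment]) -> np.ndarray:
    """Dense symmetric conflict-weight matrix with diagonal -1.

    Entries lie in [-1, 1]; pairs sharing no SNP are zero and contribute
    nothing to the clustering objective.
    """
    n = len(fragments)
    if n < 2:
        raise ValueError("need at least two fragments")
    fi, si, al, col = fragment_arrays(fragments)
    m = len(col)
    # fragment x site allele matrix, GAP where uncovered
    A = np.full((n, m), GAP, dtype=np.int8)
    A[fi, si] = al
    covered = A != GAP
    shared = (covered.astype(np.int32) @ covered.T.astype(np.int32)).astype(float)
    same = np.zeros((n, n))
    for a in range(_N_ALLELES):
        Ba = (A == a).astype(np.int32)
        same += Ba @ Ba.T
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(shared > 0, (shared - 2.0 * same) / shared, 0.0)
    np.fill_diagonal(W, -1.0)
    return W


# ---------------------------------------------------------------------------
# SDP solver


@dataclass
class SDPState:
    """Terminal state of the max-K-cut SDP solve."""

    W: np.ndarray
    K: int
    X: np.ndarray
    lam: np.ndarray  # multipliers of the elementwise bounds, i<j pairs
    Z: np.ndarray  # dual PSD matrix
    Y: np.ndarray  # augmented-Lagrangian multiplier matrix
    mu: float  # penalty parameter at termination
    sigma: float  # multiplier step (= mu)
    obj_p: float
    obj_d: float
    gap: float
    gap_tol: float
    n_iter: int
    residual: float  # max elementwise primal feasibility residual


def _project_psd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (PSD part, NSD part) of a symmetric matrix."""
    vals, vecs = np.linalg.eigh(M)
    pos = vals > 0
    P = (vecs[:, pos] * vals[pos]) @ vecs[:, pos].T
    P = (P + P.T) / 2.0
    return P, M - P


def _dual_bound(W: np.ndarray, Zc: np.ndarray, b: float) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Dual objective of an explicitly feasible dual point built from Zc.

    Decomposes W - Zc into Diag(y) + Lambda, clips negative off-diagonal
    multipliers to zero and shifts y to restore positive semidefiniteness
    of the implied Z.  The returned value is a true lower bound on the
    primal optimum.
    """
    R = W - Zc
    y = np.diag(R).copy()
    Lam = R - np.diag(np.diag(R))
    Lam_pos = np.maximum(Lam, 0.0)
    Z1 = W - np.diag(y) - Lam_pos
    Z1 = (Z1 + Z1.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(Z1)[0])
    delta = min(min_eig, 0.0)
    y_shift = y + delta
    obj_d = float(y_shift.sum() + b * Lam_pos.sum())
    Z_feas = Z1 - delta * np.eye(W.shape[0])
    return obj_d, y_shift, Lam_pos, Z_feas


def _polish_feasible(S: np.ndarray, b: float) -> np.ndarray:
    """Map a nearly feasible PSD iterate onto the exact feasible set.

    Rescaling by the diagonal keeps positive semidefiniteness and sets
    X_ii = 1 exactly; any residual box violation is removed by blending
    toward the identity (a strictly interior point), which can only
    increase the smallest eigenvalue.
    """
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    X = S / d[:, None] / d[None, :]
    np.fill_diagonal(X, 1.0)
    X = (X + X.T) / 2.0
    viol = max(0.0, float((b - X).max()))
    if viol > 0.0:
        theta = viol / (viol - b)
        X = (1.0 - theta) * X + theta * np.eye(S.shape[0])
        np.fill_diagonal(X, 1.0)
    return X


def solve_max_kcut_sdp(
    W: np.ndarray,
    K: int,
    gap_tol: float = 0.01,
    *,
    inner_tol: float = 1e-3,
    eps_feas: float = 1e-6,
    max_iter: int = 50000,
    mu0: float = 1.0,
    over_relax: float = 1.6,
    check_every: int = 25,
) -> SDPState:
    """Solve min Tr(WX) s.t. X_ii = 1, X_ij >= -1/(K-1), X PSD.

    Deterministic given (W, K, gap_tol).  The augmented-Lagrangian
    iteration runs until the splitting residual falls below ``inner_tol``
    and the relative duality gap |obj_p - obj_d| / (1 + |obj_p| + |obj_d|)
    of the *polished* primal iterate (projected exactly onto the feasible
    set) against a certified feasible dual point is at most ``gap_tol``.
    The reported X is the polished iterate, so its feasibility residuals
    are at machine precision (well below ``eps_feas``).  Raises
    :class:`SolverConvergenceError` carrying the last gap on failure.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    if K < 2:
        raise ValueError("K must be >= 2")
    n = W.shape[0]
    b = -1.0 / (K - 1)
    iu = np.triu_indices(n, 1)
    if n == 1:
        X = np.array([[1.0]])
        return SDPState(
            W=W, K=K, X=X, lam=np.empty(0), Z=np.zeros((1, 1)),
            Y=np.zeros((1, 1)), mu=mu0, sigma=mu0, obj_p=float(W[0, 0]),
            obj_d=float(W[0, 0]), gap=0.0, gap_tol=gap_tol, n_iter=0,
            residual=0.0,
        )

    def proj_box(M: np.ndarray) -> np.ndarray:
        out = np.maximum(M, b)
        np.fill_diagonal(out, 1.0)
        return out

    S = np.eye(n)
    U = np.zeros((n, n))
    mu = mu0
    gap = np.nan
    r_p = np.inf
    for it in range(1, max_iter + 1):
        X = proj_box(S - U - W / mu)
        Xr = over_relax * X + (1.0 - over_relax) * S
        M2 = Xr + U
        S_new, neg_part = _project_psd(M2)
        U = U + Xr - S_new
        r_p = float(np.abs(X - S_new).max())
        r_d = float(mu * np.abs(S_new - S).max())
        S = S_new
        if it % check_every == 0 or r_p <= inner_tol:
            X_pol = _polish_feasible(S, b)
            obj_p = float((W * X_pol).sum())
            Zc = -mu * neg_part  # exactly PSD by construction
            obj_d, y_d, Lam_pos, Z_feas = _dual_bound(W, Zc, b)
            gap = (obj_p - obj_d) / (1.0 + abs(obj_p) + abs(obj_d))
            if r_p <= inner_tol and abs(gap) <= gap_tol:
                resid = max(
                    float(np.abs(np.diag(X_pol) - 1.0).max()),
                    max(0.0, float((b - X_pol).max())),
                )
                if resid > eps_feas:  # pragma: no cover - defensive
                    raise SolverConvergenceError(
                        f"polished iterate infeasible ({resid:.3g})", gap
                    )
                return SDPState(
                    W=W, K=K, X=X_pol, lam=2.0 * Lam_pos[iu], Z=Z_feas,
                    Y=mu * U, mu=mu, sigma=mu, obj_p=obj_p, obj_d=obj_d,
                    gap=float(gap), gap_tol=gap_tol, n_iter=it,
                    residual=resid,
                )
        if it % check_every == 0:
            # rebalance the penalty when one residual stalls
            if r_p > 5.0 * r_d:
                U /= 2.0
                mu *= 2.0
            elif r_d > 5.0 * r_p and mu > 1e-4:
                U *= 2.0
                mu /= 2.0
    raise SolverConvergenceError(
        f"no convergence in {max_iter} iterations (gap {gap:.3g}, "
        f"residual {r_p:.3g})",
        gap=float(gap),
    )


# ---------------------------------------------------------------------------
# Rounding


@dataclass
class Assignment:
    """Cluster labels from randomized rounding of the SDP optimum."""

    labels: np.ndarray  # value in 0..K-1 per fragment
    K: int
    seed: int
    objective: float  # realized clustering objective sum_{same} W_ij
    mec: int | None = None


def clustering_objective(W: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Sum of W_ij over ordered same-cluster pairs (diagonal included)."""
    total = 0.0
    for k in range(K):
        mask = labels == k
        if mask.any():
            total += float(W[np.ix_(mask, mask)].sum())
    return total


def greedy_refine(
    W: np.ndarray, labels: np.ndarray, K: int, max_passes: int = 100
) -> np.ndarray:
    """Local search on the clustering objective after rounding.

    Repeatedly moves single fragments to the cluster that most decreases
    sum_{same cluster} W_ij until no improving move exists.  The objective
    strictly decreases at every move, so the search terminates; it is
    deterministic given the starting labels.
    """
    labels = np.asarray(labels).copy()
    n = labels.size
    onehot = np.zeros((K, n))
    onehot[labels, np.arange(n)] = 1.0
    T = onehot @ W  # T[k, i] = sum of W[i, j] over j in cluster k
    diag = np.diag(W)
    for _ in range(max_passes):
        moved = False
        for i in range(n):
            c = labels[i]
            # moving i from c to k changes the objective by
            # 2 * (T[k, i] - T[c, i] + W_ii)   (T[c, i] includes W_ii)
            delta = 2.0 * (T[:, i] - T[c, i] + diag[i])
            k = int(np.argmin(delta))
            if delta[k] < -1e-9:
                T[c] -= W[i]
                T[k] += W[i]
                labels[i] = k
                moved = True
        if not moved:
            break
    return labels


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (permutation-invariant)."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        out[i] = mapping.setdefault(int(l), len(mapping))
    return out


def mec_refine(
    fi: np.ndarray,
    si: np.ndarray,
    al: np.ndarray,
    labels: np.ndarray,
    K: int,
    n_sites: int,
    max_iter: int = 30,
) -> np.ndarray:
    """Coordinate descent on the MEC objective.

    Alternates majority-vote consensus with reassignment of every fragment
    to the cluster whose consensus it mismatches least (ties keep the
    current label).  Each step is non-increasing in the assigned-cluster
    mismatch total, so the iteration terminates.  This is the natural
    polish for polyploid data, where the pairwise clustering objective can
    prefer partitions that mix chance-agreeing haplotypes: MEC is the
    compatibility criterion the assembly is judged by.
    """
    labels = np.asarray(labels).copy()
    n = labels.size
    for _ in range(max_iter):
        consensus, _ = consensus_arrays(fi, si, al, labels, K, n_sites)
        d = np.zeros((n, K), dtype=np.int64)
        for k in range(K):
            hap = consensus[k]
            mism = (hap[si] != GAP) & (hap[si] != al)
            np.add.at(d[:, k], fi[mism], 1)
        best = np.argmin(d, axis=1)
        # keep the current label on ties
        keep = d[np.arange(n), labels] == d[np.arange(n), best]
        new = np.where(keep, labels, best)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def round_assignment(
    state: SDPState,
    restarts: int = 100,
    rng_seed: int = 0,
    fragments: Sequence[Fragment] | None = None,
    select: str | None = None,
    refine: bool = True,
) -> Assignment:
    """Randomized rounding of the SDP optimum into K cluster labels.

    Per restart, K i.i.d. standard-normal N-vectors are drawn and fragment
    i receives the label whose vector maximizes the inner product with
    column i of X; a deterministic greedy local search on the clustering
    objective then repairs single-fragment misassignments (disable both
    polish steps with ``refine=False``).  When fragments are available the
    labels are additionally polished by MEC coordinate descent
    (:func:`mec_refine`).  Among restarts the assignment minimizing the
    consensus MEC is kept, ties broken by the clustering objective
    (``select="mec"``, requires ``fragments``); without fragments the
    objective alone is minimized (``select="objective"``).  Deterministic
    given ``rng_seed``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if select is None:
        select = "mec" if fragments is not None else "objective"
    if select == "mec" and fragments is None:
        raise ValueError("MEC selection needs the fragments")
    X, K = state.X, state.K
    n = X.shape[0]
    rng = np.random.default_rng(rng_seed)
    if fragments is not None:
        fi, si, al, col = fragment_arrays(fragments)
        n_sites = len(col)
    best: Assignment | None = None
    best_key: tuple | None = None
    seen: dict[bytes, tuple[np.ndarray, float, int | None]] = {}
    for _ in range(restarts):
        V = rng.standard_normal((K, n))
        labels = np.argmax(V @ X, axis=0)
        # cache on the partition, not the arbitrary cluster names
        cache_key = _canonical_labels(labels).tobytes()
        if cache_key in seen:
            labels, obj, mec_val = seen[cache_key]
        else:
            raw_key = cache_key
            if refine:
                labels = greedy_refine(state.W, labels, K)
                if fragments is not None:
                    labels = mec_refine(fi, si, al, labels, K, n_sites)
            obj = clustering_objective(state.W, labels, K)
            mec_val = None
            if fragments is not None:
                consensus, _ = consensus_arrays(fi, si, al, labels, K, n_sites)
                mec_val = int(_mec_from_arrays(fi, si, al, consensus))
            seen[raw_key] = (labels, obj, mec_val)
        key = (mec_val, obj) if select == "mec" else (obj,)
        if best_key is None or key < best_key:
            best_key = key
            best = Assignment(
                labels=labels, K=K, seed=rng_seed, objective=obj, mec=mec_val
            )
    assert best is not None
    if len(np.unique(best.labels)) == 1 and n > 1:
        warnings.warn("rounding placed all fragments in one cluster")
    return best


# ---------------------------------------------------------------------------
# Consensus


@dataclass
class HaplotypeBlock:
    """K phased allele sequences over a set of variant indices.

    ``haplotypes`` is a (K, L) array of allele codes with ``GAP`` (-1) at
    uncovered positions; ``support`` counts, per haplotype and site, the
    fragment calls matching the consensus allele.
    """

    variant_indices: tuple[int, ...]
    haplotypes: np.ndarray
    support: np.ndarray
    mec: int
    n_fragments: int
    metadata: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.variant_indices)


def consensus_arrays(
    fi: np.ndarray,
    si: np.ndarray,
    al: np.ndarray,
    labels: np.ndarray,
    K: int,
    n_sites: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote consensus per (cluster, site) from flattened calls.

    Returns (consensus, support): consensus is (K, n_sites) with GAP where
    no cluster fragment covers the site; ties prefer the lowest allele
    code.  Support is the matching-call count at the chosen allele.
    """
    counts = np.zeros((K, n_sites, _N_ALLELES), dtype=np.int64)
    np.add.at(counts, (labels[fi], si, al), 1)
    total = counts.sum(axis=2)
    consensus = np.argmax(counts, axis=2)  # first max -> lowest allele code
    support = np.take_along_axis(counts, consensus[:, :, None], axis=2)[:, :, 0]
    consensus = np.where(total > 0, consensus, GAP)
    support = np.where(total > 0, support, 0)
    return consensus.astype(np.int64), support


def _mec_from_arrays(
    fi: np.ndarray, si: np.ndarray, al: np.ndarray, consensus: np.ndarray
) -> int:
    """MEC = sum over fragments of the distance to the nearest haplotype.

    Only haplotypes sharing at least one covered (non-gap) site with the
    fragment are eligible: a haplotype that never overlaps a fragment
    cannot explain it, otherwise an all-gap haplotype would absorb every
    fragment at zero cost.
    """
    n = int(fi.max()) + 1 if fi.size else 0
    K = consensus.shape[0]
    d = np.zeros((n, K), dtype=np.int64)
    overlap = np.zeros((n, K), dtype=np.int64)
    for k in range(K):
        hap = consensus[k]
        covered = hap[si] != GAP
        mism = covered & (hap[si] != al)
        np.add.at(d[:, k], fi[mism], 1)
        np.add.at(overlap[:, k], fi[covered], 1)
    d = np.where(overlap > 0, d, np.iinfo(np.int64).max)
    best = d.min(axis=1)
    return int(best[best < np.iinfo(np.int64).max].sum())


def consensus_haplotypes(
    fragments: Sequence[Fragment],
    assignment: Assignment | np.ndarray,
    K: int,
) -> HaplotypeBlock:
    """Collapse labeled fragments into K haplotypes by majority voting."""
    labels = assignment.labels if isinstance(assignment, Assignment) else np.asarray(assignment)
    if len(labels) != len(fragments):
        raise ValueError("one label per fragment required")
    fi, si, al, col = fragment_arrays(fragments)
    n_sites = len(col)
    consensus, support = consensus_arrays(fi, si, al, labels, K, n_sites)
    for k in range(K):
        if not np.any(labels == k):
            warnings.warn(f"cluster {k} is empty; haplotype {k} is all gaps")
    mec = _mec_from_arrays(fi, si, al, consensus)
    sites = tuple(sorted(col, key=col.get))
    return HaplotypeBlock(
        variant_indices=sites,
        haplotypes=consensus,
        support=support,
        mec=mec,
        n_fragments=len(fragments),
    )


# ---------------------------------------------------------------------------
# Component assembly and the brute-force oracle


@dataclass(frozen=True)
class SolverConfig:
    """Knobs of the assembly core."""

    gap_tol: float = 0.01
    restarts: int = 100
    seed: int = 0
    max_iter: int = 50000


def assemble_component(
    fragments: Sequence[Fragment],
    K: int,
    solver_cfg: SolverConfig = SolverConfig(),
    component_id: str | None = None,
) -> HaplotypeBlock:
    """Full assembly of one strongly connected component."""
    if len(fragments) < K:
        raise ValueError(
            f"underdetermined component: {len(fragments)} fragments < ploidy {K}"
        )
    W = build_conflict_weights(fragments)
    state = solve_max_kcut_sdp(
        W, K, gap_tol=solver_cfg.gap_tol, max_iter=solver_cfg.max_iter
    )
    assignment = round_assignment(
        state, restarts=solver_cfg.restarts, rng_seed=solver_cfg.seed,
        fragments=fragments,
    )
    block = consensus_haplotypes(fragments, assignment, K)
    block.metadata.update(
        component=component_id,
        seed=solver_cfg.seed,
        restarts=solver_cfg.restarts,
        sdp_gap=state.gap,
        sdp_iterations=state.n_iter,
        objective=assignment.objective,
    )
    return block


def brute_force_max_kcut(W: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Exhaustive minimum of the clustering objective over K^N labelings.

    Test oracle only (refuses N > 12).  Labelings are enumerated in
    lexicographic order and the first minimizer is returned, so the result
    is deterministic.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n > 12:
        raise ValueError("brute force limited to N <= 12")
    best_obj = np.inf
    best_labels: tuple[int, ...] | None = None
    for labels in itertools.product(range(K), repeat=n):
        arr = np.asarray(labels)
        obj = clustering_objective(W, arr, K)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_labels = labels
    assert best_labels is not None
    return np.asarray(best_labels), float(best_obj)
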