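"""Independent Subspace Analysis by maximum likelihood on whitened patches.

The model is an orthonormal component matrix W (rows are analysis filters in
whitened space) whose rows are grouped into fixed consecutive subspaces of
``subunits_per_subspace`` members.  The per-patch log-likelihood is, up to
constants, the sum over subspaces of G(u) with u the squared subspace
response norm and G(u) = -sqrt(u + eps): responses are Gaussian (isotropic)
within a subspace, and the square root makes the subspace norms sparse
across subspaces.

The optimiser is full-batch gradient ascent on W with symmetric
re-orthogonalisation after every step and a backtracking step-size: simple,
deterministic under a fixed seed, and adequate at the problem sizes used
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .patches import PatchMatrix, WhiteningTransform

__all__ = [
    "ISAOptions",
    "ISAModel",
    "subspace_norm",
    "isa_objective",
    "fit_isa",
    "subspace_recovery_score",
]


@dataclass
class ISAOptions:
    """Tunables for the maximum-likelihood fit.

    eps smooths the square-root nonlinearity at zero; step0 is the initial
    gradient-ascent step, grown by step_grow on success and halved on
    backtracking.  Convergence: |objective change| < tol for ``patience``
    consecutive accepted iterations, capped at max_iter.
    """

    eps: float = 1e-4
    step0: float = 0.5
    step_grow: float = 1.2
    max_iter: int = 500
    tol: float = 1e-7
    patience: int = 5
    n_restarts: int = 5
    burn_in: int = 150
    polish_rounds: int = 20
    polish_max_iter: int = 100
    resplit_rounds: int = 3
    resplit_pairs_per_subspace: float = 3.0
    resplit_max_rows: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ISAModel:
    """Learned orthonormal components grouped into subspaces.

    W has J = n_subspaces * subunits_per_subspace rows in whitened space;
    row j belongs to subspace j // subunits_per_subspace.  A = W.T is the
    mixing matrix back to whitened space (W has orthonormal rows).
    """

    W: np.ndarray
    n_subspaces: int
    subunits_per_subspace: int
    whitening: WhiteningTransform | None = None
    objective_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    options: ISAOptions | None = None

    @property
    def subspace_of(self) -> np.ndarray:
        return np.arange(self.W.shape[0]) // self.subunits_per_subspace

    @property
    def A(self) -> np.ndarray:
        return self.W.T

    def subunit_rows(self, s: int) -> np.ndarray:
        if not 0 <= s < self.n_subspaces:
            raise IndexError(f"subspace index {s} out of range [0, {self.n_subspaces})")
        d = self.subunits_per_subspace
        return self.W[s * d : (s + 1) * d]


def _as_array(z) -> np.ndarray:
    if isinstance(z, PatchMatrix):
        return z.data
    return np.asarray(z, dtype=float)


def subspace_norm(model: ISAModel, s: int, z: np.ndarray) -> float:
    """sqrt of the summed squared subunit responses of subspace ``s`` to ``z``."""
    rows = model.subunit_rows(s)
    return float(np.sqrt(np.sum((rows @ np.asarray(z, dtype=float)) ** 2)))


def _subspace_energies(w: np.ndarray, z: np.ndarray, n_subspaces: int, d: int) -> np.ndarray:
    """N x S matrix of squared subspace norms."""
    y = z @ w.T  # N x J
    return (y ** 2).reshape(z.shape[0], n_subspaces, d).sum(axis=2), y


def isa_objective(model: ISAModel, z, opts: ISAOptions | None = None) -> float:
    """Mean per-patch log-likelihood (up to constants); higher is sparser."""
    opts = opts or model.options or ISAOptions()
    zz = _as_array(z)
    u, _ = _subspace_energies(model.W, zz, model.n_subspaces, model.subunits_per_subspace)
    return float(-np.sqrt(u + opts.eps).sum(axis=1).mean())


def _objective_only(w, z, n_subspaces, d, eps):
    """Objective plus the response matrix, for cheap backtracking probes."""
    u, y = _subspace_energies(w, z, n_subspaces, d)
    root = np.sqrt(u + eps)
    return float(-root.sum(axis=1).mean()), y, root


def _grad_from_responses(y, root, z, d):
    # dG/du = -1/(2 sqrt(u+eps)); dobj/dW_j = (2/N) sum_i dG/du * y_ij * z_i
    n = z.shape[0]
    coef = np.repeat(-0.5 / root, d, axis=1)  # N x J
    return (2.0 / n) * (coef * y).T @ z


def _objective_and_grad(w, z, n_subspaces, d, eps):
    obj, y, root = _objective_only(w, z, n_subspaces, d, eps)
    return obj, _grad_from_responses(y, root, z, d)


def _best_swap(w, z, n_subspaces, d, eps, min_gain):
    """Best objective gain from exchanging one row between two subspaces."""
    if n_subspaces < 2:
        return None
    n = z.shape[0]
    y = z @ w.T
    y2 = y ** 2
    u = y2.reshape(n, n_subspaces, d).sum(axis=2)
    root = np.sqrt(u + eps)
    base = root.sum(axis=1)
    best = None
    best_gain = min_gain
    j_total = n_subspaces * d
    for a in range(j_total):
        sa = a // d
        for b in range(a + 1, j_total):
            sb = b // d
            if sb == sa:
                continue
            ua = u[:, sa] - y2[:, a] + y2[:, b]
            ub = u[:, sb] - y2[:, b] + y2[:, a]
            new = base - root[:, sa] - root[:, sb] + np.sqrt(ua + eps) + np.sqrt(ub + eps)
            gain = float((base - new).mean())  # objective is -mean(sum sqrt)
            if gain > best_gain:
                best_gain = gain
                best = (a, b, gain)
    return best


def _resplit_pass(w, z, n_subspaces, d, opts):
    """Try re-splitting the spans of energy-correlated subspace pairs."""
    n = z.shape[0]
    u, _ = _subspace_energies(w, z, n_subspaces, d)
    corr = np.corrcoef(u.T)
    np.fill_diagonal(corr, -np.inf)
    pairs = [(corr[s, t], s, t) for s in range(n_subspaces) for t in range(s + 1, n_subspaces)]
    pairs.sort(reverse=True)
    n_try = max(1, int(opts.resplit_pairs_per_subspace * n_subspaces))
    sub_opts = ISAOptions(
        eps=opts.eps, step0=opts.step0, step_grow=opts.step_grow,
        max_iter=150, tol=opts.tol, patience=opts.patience,
        n_restarts=4, burn_in=60, polish_rounds=2, resplit_rounds=0,
        seed=(opts.seed + 1) % (2 ** 31),
    )
    # A deterministic row subsample is plenty to judge a 2d-dim re-split.
    if n > opts.resplit_max_rows:
        zs = z[:: int(np.ceil(n / opts.resplit_max_rows))]
    else:
        zs = z
    w = w.copy()
    n_applied = 0
    touched: set[int] = set()
    for _c, s, t in pairs[:n_try]:
        if s in touched or t in touched:
            continue
        rows = np.vstack([w[s * d : (s + 1) * d], w[t * d : (t + 1) * d]])
        yp = zs @ rows.T  # N x 2d; identity covariance since rows orthonormal
        old = float(
            -(np.sqrt((yp[:, :d] ** 2).sum(1) + opts.eps)
              + np.sqrt((yp[:, d:] ** 2).sum(1) + opts.eps)).mean()
        )
        sub = fit_isa(yp, 2, d, sub_opts)
        new = float(sub.objective_trace[-1])
        if new > old + 10 * opts.tol:
            rotated = sub.W @ rows
            w[s * d : (s + 1) * d] = rotated[:d]
            w[t * d : (t + 1) * d] = rotated[d:]
            touched.update((s, t))
            n_applied += 1
    return w, n_applied


def _sym_orth(w: np.ndarray) -> np.ndarray:
    """Symmetric orthogonalisation: (W W^T)^(-1/2) W."""
    gram = w @ w.T
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("component matrix lost rank during optimisation")
    inv_root = (vecs / np.sqrt(vals)) @ vecs.T
    return inv_root @ w


def fit_isa(
    z,
    n_subspaces: int,
    subunits_per_subspace: int = 2,
    opts: ISAOptions | None = None,
    whitening: WhiteningTransform | None = None,
) -> ISAModel:
    """Fit the subspace model to whitened data by gradient ascent.

    The objective never decreases across accepted iterations (backtracking
    halves the step otherwise) and W is re-orthogonalised after every step.
    """
    opts = opts or ISAOptions()
    zz = _as_array(z)
    n, k = zz.shape
    j = n_subspaces * subunits_per_subspace
    if j > k:
        raise ValueError(
            f"{n_subspaces}x{subunits_per_subspace} components exceed whitened dimension {k}"
        )

    def ascend(state, max_iter):
        w, obj, grad, step, trace = state
        still = 0
        converged = False
        for _ in range(max_iter):
            accepted = False
            for _ in range(40):
                cand = _sym_orth(w + step * grad)
                cand_obj, y, root = _objective_only(
                    cand, zz, n_subspaces, subunits_per_subspace, opts.eps
                )
                if not np.isfinite(cand_obj):
                    raise FloatingPointError("ISA objective diverged (non-finite value)")
                if cand_obj >= obj:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                converged = True  # no ascent direction at machine precision
                break
            delta = cand_obj - obj
            w, obj = cand, cand_obj
            grad = _grad_from_responses(y, root, zz, subunits_per_subspace)
            trace.append(obj)
            step *= opts.step_grow
            still = still + 1 if delta < opts.tol else 0
            if still >= opts.patience:
                converged = True
                break
        return (w, obj, grad, step, trace), converged

    # The likelihood surface has local optima where subspaces stay mixed, so
    # several random inits are burned in and the best objective is pursued.
    candidates = []
    for r in range(max(1, opts.n_restarts)):
        rng = np.random.default_rng((opts.seed, r))
        w0 = _sym_orth(rng.standard_normal((j, k)))
        obj0, grad0 = _objective_and_grad(
            w0, zz, n_subspaces, subunits_per_subspace, opts.eps
        )
        state, done = ascend((w0, obj0, grad0, opts.step0, [obj0]), opts.burn_in)
        candidates.append((state, done))
    best_idx = int(np.argmax([s[1] for s, _ in candidates]))
    state, converged = candidates[best_idx]
    if not converged:
        state, converged = ascend(state, opts.max_iter)

    # Grouping polish: a converged solution can still pair components with
    # the wrong subspace partners.  Swapping two rows between subspaces only
    # re-bins already-computed responses, so every candidate swap is scored
    # incrementally; each accepted swap is followed by a fresh ascent.
    # Gains below ~10x the convergence tolerance are numerical dust and
    # would keep the polish loop spinning without changing the solution.
    min_gain = 10.0 * opts.tol
    for _ in range(opts.polish_rounds):
        w, obj, grad, step, trace = state
        swap = _best_swap(w, zz, n_subspaces, subunits_per_subspace, opts.eps,
                          min_gain)
        if swap is None:
            break
        a, b, _gain = swap
        w = w.copy()
        w[[a, b]] = w[[b, a]]
        obj2, grad2 = _objective_and_grad(
            w, zz, n_subspaces, subunits_per_subspace, opts.eps
        )
        trace.append(obj2)
        state, converged = ascend((w, obj2, grad2, opts.step0, trace),
                                  opts.polish_max_iter)

    # Merge-and-resplit polish: two subspaces can jointly span the right
    # space yet split it along the wrong planes, which no row swap repairs.
    # Candidate pairs are ranked by the correlation of their response
    # energies (independent subspaces have uncorrelated energies) and each
    # candidate's 2d-dimensional span is re-split by a small recursive fit.
    for _ in range(opts.resplit_rounds if n_subspaces >= 2 else 0):
        w, obj, grad, step, trace = state
        w, n_applied = _resplit_pass(w, zz, n_subspaces, subunits_per_subspace, opts)
        if n_applied == 0:
            break
        obj2, grad2 = _objective_and_grad(
            w, zz, n_subspaces, subunits_per_subspace, opts.eps
        )
        trace.append(obj2)
        state, converged = ascend((w, obj2, grad2, opts.step0, trace),
                                  opts.polish_max_iter)
    w, obj, grad, step, trace = state

    return ISAModel(
        W=w,
        n_subspaces=n_subspaces,
        subunits_per_subspace=subunits_per_subspace,
        whitening=whitening,
        objective_trace=np.asarray(trace),
        converged=converged,
        options=opts,
    )


def _orthonormal_basis(rows: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(rows.T)
    return q  # M x d


def subspace_recovery_score(
    learned: np.ndarray,
    true: np.ndarray,
    subunits_per_subspace: int,
) -> float:
    """Mean principal-angle cosine between matched learned and true subspaces.

    Both inputs are J x M filter matrices whose consecutive
    ``subunits_per_subspace`` rows form one subspace.  Subspaces are matched
    by maximising the Frobenius inner product of their orthogonal projectors
    (Hungarian assignment); the score averages the principal-angle cosines of
    the matched pairs.  1.0 means exact recovery up to within-subspace
    rotation and subspace permutation; chance level for random d-dim
    subspaces of an M-dim space is about sqrt(d/M).
    """
    learned = np.asarray(learned, dtype=float)
    true = np.asarray(true, dtype=float)
    if learned.shape != true.shape:
        raise ValueError("learned and true filter matrices must have equal shapes")
    d = subunits_per_subspace
    s = learned.shape[0] // d
    bases_l = [_orthonormal_basis(learned[i * d : (i + 1) * d]) for i in range(s)]
    bases_t = [_orthonormal_basis(true[i * d : (i + 1) * d]) for i in range(s)]
    # <P_a, P_b>_F = ||Qa^T Qb||_F^2 = sum of squared principal-angle cosines
    overlap = np.array(
        [[np.sum((bl.T @ bt) ** 2) for bt in bases_t] for bl in bases_l]
    )
    row, col = linear_sum_assignment(-overlap)
    cosines = []
    for a, b in zip(row, col):
        sv = np.linalg.svd(bases_l[a].T @ bases_t[b], compute_uv=False)
        cosines.extend(np.clip(sv, 0.0, 1.0))
    return float(np.mean(cosines))
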