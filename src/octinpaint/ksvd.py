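"""K-SVD dictionary learning.

Alternates (i) batch-OMP sparse coding of all training vectors against
the current dictionary with (ii) a sequential atom update: for each atom,
the representation-error matrix restricted to the signals that use it is
approximated by its best rank-1 factorization; the atom is replaced by the
leading singular direction and the corresponding coefficients are updated
in the same step.

Two housekeeping devices keep the factorization out of local minima and
the objective provably non-increasing:

* *Monotone coding.*  Greedy OMP re-coding is not guaranteed to beat the
  codes carried over from the previous iteration.  After each coding pass
  the few signals whose re-code is worse are reverted to their previous
  code — but only as many (worst offenders first) as needed to keep the
  mean squared representation error non-increasing, so exploration by
  support switching is preserved.
* *Atom re-seeding.*  Atoms that no signal uses, and near-duplicate atom
  pairs (|inner product| > 0.99, which code the same structure), are
  re-seeded from the worst-represented training vectors; the seeding
  signal simultaneously receives the exact 1-sparse code on its new atom.
  A duplicate's coefficients are folded into its twin first, and the whole
  purge is rolled back in the rare case it would raise the total error.

Columns stay unit-norm with a fixed sign convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary, _apply_sign_convention
from .omp import batch_omp_arrays

log = logging.getLogger(__name__)

#: Defaults for training on display-domain (8-bit-range) OCT patches.
DEFAULT_EPSILON = 5.28
DEFAULT_N_ATOMS = 128
DEFAULT_ITERATIONS = 20
DEFAULT_PATCH_SIZE = (8, 8)

_DUPLICATE_COHERENCE = 0.99


@dataclass(frozen=True)
class TrainingConfig:
    """K-SVD hyper-parameters.

    ``epsilon`` is the per-patch squared-ℓ2 representation-error target on
    the 8-bit intensity scale (the coding step stops adding atoms once the
    residual reaches it); ``max_sparsity`` additionally caps the number of
    atoms per training code (``None`` → a quarter of the patch dimension),
    which bounds the coding cost when the error target is tight relative
    to the noise floor.  Set ``epsilon=None`` for purely
    sparsity-constrained training.
    """

    epsilon: float | None = DEFAULT_EPSILON
    n_atoms: int = DEFAULT_N_ATOMS
    iterations: int = DEFAULT_ITERATIONS
    patch_size: tuple[int, int] = DEFAULT_PATCH_SIZE
    seed: int = 0
    max_sparsity: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive (or None)")
        if self.epsilon is None and self.max_sparsity is None:
            raise ValueError("need epsilon and/or max_sparsity")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")

    def effective_sparsity_cap(self, dim: int) -> int:
        if self.max_sparsity is not None:
            return min(self.max_sparsity, dim, self.n_atoms)
        return max(4, min(dim // 4, self.n_atoms))


class _KSVDState:
    """Mutable training state: dictionary A, codes C, residuals R."""

    def __init__(self, Y: np.ndarray, A: np.ndarray):
        self.Y = Y
        self.A = A
        self.C = np.zeros((Y.shape[0], A.shape[1]))
        self.R = Y.copy()

    def reseed_atom(self, j: int, i: int) -> float:
        """Replace atom j with normalized signal i and give signal i the
        exact 1-sparse code on it.  Returns the change in that signal's
        squared residual (negative = improvement)."""
        Y, A, C, R = self.Y, self.A, self.C, self.R
        old_res = float(R[i] @ R[i])
        C[i, np.flatnonzero(C[i])] = 0.0
        atom = Y[i] / np.linalg.norm(Y[i])
        atom = _apply_sign_convention(atom[:, None])[:, 0]
        A[:, j] = atom
        C[i, j] = Y[i] @ atom
        R[i] = Y[i] - C[i, j] * atom
        return float(R[i] @ R[i]) - old_res


def _init_dictionary(Y: np.ndarray, q: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Seed the dictionary with q random distinct training vectors."""
    norms = np.linalg.norm(Y, axis=1)
    candidates = np.flatnonzero(norms > 1e-10)
    if candidates.size < q:
        raise ValueError("too few non-degenerate training vectors")
    pick = rng.choice(candidates, size=q, replace=False)
    A = (Y[pick] / norms[pick, None]).T
    return _apply_sign_convention(A)


def _monotone_coding(st: _KSVDState, C_new: np.ndarray, res_new: np.ndarray,
                     prev_mean: float | None) -> np.ndarray:
    """Accept the new codes, reverting worst offenders if needed to keep
    the mean squared error non-increasing.  Returns per-signal residuals."""
    Y, A = st.Y, st.A
    if prev_mean is None:
        st.C = C_new
        return res_new
    R_prev = Y - st.C @ A.T
    res_prev = np.einsum("ij,ij->i", R_prev, R_prev)
    n = Y.shape[0]
    target = min(float(res_prev.mean()), prev_mean) * n
    delta = res_new - res_prev
    excess = float(res_new.sum()) - target
    if excess > 0:
        order = np.argsort(-delta)
        cum = np.cumsum(delta[order])
        k = int(np.searchsorted(cum, excess - 1e-12)) + 1
        k = min(k, int((delta > 0).sum()))
        rev = order[:k]
        C_new[rev] = st.C[rev]
        res_new = res_new.copy()
        res_new[rev] = res_prev[rev]
    st.C = C_new
    return res_new


def _update_atoms(st: _KSVDState) -> None:
    """One sequential sweep of rank-1 atom updates (ascending index)."""
    A, C, R, Y = st.A, st.C, st.R, st.Y
    for j in range(A.shape[1]):
        users = np.flatnonzero(C[:, j])
        if users.size == 0:
            res = np.einsum("ij,ij->i", R, R)
            for i in np.argsort(-res):
                if np.linalg.norm(Y[i]) > 1e-10:
                    st.reseed_atom(j, int(i))
                    break
            continue
        Ej = R[users] + np.outer(C[users, j], A[:, j])
        _, V = np.linalg.eigh(Ej.T @ Ej)   # exact rank-1 (small dim)
        atom = _apply_sign_convention(V[:, -1][:, None])[:, 0]
        coef = Ej @ atom
        A[:, j] = atom
        C[users, j] = coef
        R[users] = Ej - np.outer(coef, atom)


def _purge_duplicates(st: _KSVDState) -> None:
    """Re-seed near-duplicate atoms from poorly represented signals.

    The duplicate's coefficients are folded into its twin so the
    representation barely moves; the purge is rolled back entirely if it
    would raise the total squared error (rare, keeps the objective
    monotone).
    """
    A, C, R, Y = st.A, st.C, st.R, st.Y
    q = A.shape[1]
    G = A.T @ A
    res = np.einsum("ij,ij->i", R, R)
    order = np.argsort(-res)
    nxt = 0
    for j in range(q):
        twins = np.flatnonzero(np.abs(G[j, :j]) > _DUPLICATE_COHERENCE)
        if twins.size == 0:
            continue
        keep = int(twins[0])
        users = np.flatnonzero(C[:, j])
        atom_save = A[:, j].copy()
        bump = 0.0
        old = None
        sign = 1.0
        if users.size:
            sign = float(np.sign(G[j, keep]) or 1.0)
            old = C[users, j].copy()
            dr = np.outer(old, atom_save - sign * A[:, keep])
            bump = float(np.einsum("ij,ij->", 2 * R[users] + dr, dr))
            C[users, keep] += sign * old
            C[users, j] = 0.0
            R[users] += dr
        seed_i = None
        while nxt < order.size:
            cand = int(order[nxt])
            nxt += 1
            if np.linalg.norm(Y[cand]) > 1e-10:
                seed_i = cand
                break
        gain = st.reseed_atom(j, seed_i) if seed_i is not None else 0.0
        if bump + gain > 1e-12:
            # net harm: roll everything back
            if seed_i is not None:
                C[seed_i, np.flatnonzero(C[seed_i])] = 0.0
                R[seed_i] = Y[seed_i]
            A[:, j] = atom_save
            if users.size:
                C[users, keep] -= sign * old
                C[users, j] = old
                R[users] -= np.outer(old, atom_save - sign * A[:, keep])
            continue
        G[j, :] = A[:, j] @ A
        G[:, j] = G[j, :]


def ksvd_train(training_vectors: np.ndarray, cfg: TrainingConfig
               ) -> Dictionary:
    """Learn an overcomplete dictionary from zero-mean training vectors.

    Parameters
    ----------
    training_vectors
        (n, ab) array of standardized (zero-mean) patch vectors; needs at
        least ``cfg.n_atoms`` rows.

    Returns
    -------
    Dictionary with unit-norm atoms; ``metadata['error_history']`` holds
    the mean squared representation error after each coding pass
    (non-increasing across iterations).
    """
    Y = np.asarray(training_vectors, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("training vectors must be a 2-D (n, ab) array")
    n, dim = Y.shape
    a, b = cfg.patch_size
    if dim != a * b:
        raise ValueError("vector length must equal patch a*b")
    if n < cfg.n_atoms:
        raise ValueError("need at least n_atoms training vectors")
    if np.allclose(Y, Y[0]):
        raise ValueError("degenerate training data (all vectors identical)")

    rng = np.random.default_rng(cfg.seed)
    st = _KSVDState(Y, _init_dictionary(Y, cfg.n_atoms, rng))
    cap = cfg.effective_sparsity_cap(dim)

    history: list[float] = []
    for it in range(cfg.iterations):
        C_new, res_sq, _ = batch_omp_arrays(
            st.A, Y, max_sparsity=cap, error_target=cfg.epsilon)
        res_sq = _monotone_coding(st, C_new, res_sq,
                                  history[-1] if history else None)
        history.append(float(res_sq.mean()))
        log.info("K-SVD iteration %d/%d: mean squared error %.4f",
                 it + 1, cfg.iterations, history[-1])
        st.R = Y - st.C @ st.A.T
        _update_atoms(st)
        _purge_duplicates(st)

    return Dictionary(
        atoms=st.A,
        patch_shape=cfg.patch_size,
        metadata={
            "epsilon": cfg.epsilon,
            "iterations": cfg.iterations,
            "seed": cfg.seed,
            "max_sparsity": cap,
            "n_training": n,
            "error_history": history,
        },
    )
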