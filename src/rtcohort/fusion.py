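"""Multi-rater binary label fusion: majority voting and STAPLE.

STAPLE (simultaneous truth and performance level estimation) treats the
unknown true segmentation as a latent binary field and each rater j as a
noisy channel with sensitivity p_j = P(D=1 | T=1) and specificity
q_j = P(D=0 | T=0).  EM alternates:

* E-step: per-voxel consensus probability
  W_i = f * prod_j p_j^D (1-p_j)^(1-D)
        / [ that + (1-f) * prod_j (1-q_j)^D q_j^(1-D) ]
  with fixed prior prevalence f;
* M-step: p_j = sum_i W_i D_ij / sum_i W_i,
          q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i).

Iteration stops when max(|dp|, |dq|) < tol or at max_iter.  The fused
mask is {W_i >= threshold}; the conventional threshold is 50%.

For tractability and to keep the vast empty background from swamping
specificity, the EM sums run only over the bounding box of the union of
rater masks dilated by one voxel; the all-background voxels outside the
box share a single closed-form W and enter the M-step analytically, so
the result is identical to running EM over the full grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from rtcohort.geometry import BinaryMask
from rtcohort.rt_model import ValidationError

_CLAMP = 1e-6  # keeps p, q off 0/1 and products out of log-domain trouble


class FusionError(ValidationError):
    pass


@dataclass
class RaterStack:
    """N rater masks on one common grid, stacked (n_raters, nz, ny, nx)."""

    masks: list[BinaryMask]

    def __post_init__(self):
        if not self.masks:
            raise FusionError("empty rater stack")
        first = self.masks[0]
        for m in self.masks[1:]:
            if not first.same_grid(m):
                raise FusionError("rater masks on mismatched grids")

    @property
    def n_raters(self) -> int:
        return len(self.masks)

    @property
    def decisions(self) -> np.ndarray:
        return np.stack([m.voxels for m in self.masks])

    @property
    def grid(self):
        return self.masks[0].grid


@dataclass
class StapleState:
    """Converged EM parameters and the consensus probability field."""

    sensitivity: np.ndarray  # p_j, per rater
    specificity: np.ndarray  # q_j, per rater
    consensus: np.ndarray  # W_i, full grid, float
    prevalence: float
    n_iter: int
    converged: bool


def majority_vote(stack: RaterStack) -> BinaryMask:
    """Strict majority: voxel true iff more than n/2 raters mark it.

    Ties with an even rater count are background.
    """
    votes = stack.decisions.sum(axis=0)
    return BinaryMask(grid=stack.grid, voxels=votes > stack.n_raters / 2.0)


def staple(
    stack: RaterStack,
    threshold: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    init_performance: float = 0.99,
) -> tuple[BinaryMask, StapleState]:
    """STAPLE fusion of a rater stack.

    Requires >= 2 raters and a non-degenerate stack (at least one voxel
    marked by someone and at least one marked by no one).  Non-convergence
    within ``max_iter`` returns the current estimate with a warning.
    """
    if stack.n_raters < 2:
        raise FusionError("STAPLE needs at least 2 raters")
    D_full = stack.decisions
    union = D_full.any(axis=0)
    if not union.any():
        raise FusionError("degenerate stack: no rater marked any voxel")
    if union.all():
        raise FusionError("degenerate stack: every voxel marked by some rater")

    # bounding box of the union, dilated by one voxel
    idx = np.nonzero(union)
    lo = [max(int(a.min()) - 1, 0) for a in idx]
    hi = [min(int(a.max()) + 2, s) for a, s in zip(idx, union.shape)]
    box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    D = D_full[(slice(None),) + box].reshape(stack.n_raters, -1).astype(float)
    n_total = union.size
    n_box = D.shape[1]
    n_out = n_total - n_box  # all-background voxels handled in closed form

    f = float(D_full.mean())  # prior prevalence: mean rater foreground fraction
    p = np.full(stack.n_raters, init_performance)
    q = np.full(stack.n_raters, init_performance)

    W = np.empty(n_box)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log domain)
        log_a = np.log(f) + (D * np.log(p[:, None]) + (1 - D) * np.log1p(-p[:, None])).sum(axis=0)
        log_b = np.log1p(-f) + (D * np.log1p(-q[:, None]) + (1 - D) * np.log(q[:, None])).sum(axis=0)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        W = a / (a + b)
        # outside the box every rater says 0
        log_a0 = np.log(f) + np.log1p(-p).sum()
        log_b0 = np.log1p(-f) + np.log(q).sum()
        m0 = max(log_a0, log_b0)
        w_out = np.exp(log_a0 - m0) / (np.exp(log_a0 - m0) + np.exp(log_b0 - m0))

        # M-step, with the n_out background voxels counted analytically
        sum_w = W.sum() + n_out * w_out
        sum_not_w = (n_box - W.sum()) + n_out * (1.0 - w_out)
        p_new = (D * W).sum(axis=1) / sum_w
        q_new = ((1 - D) * (1 - W)).sum(axis=1) + n_out * (1.0 - w_out)
        q_new = q_new / sum_not_w
        p_new = np.clip(p_new, _CLAMP, 1 - _CLAMP)
        q_new = np.clip(q_new, _CLAMP, 1 - _CLAMP)

        delta = max(np.max(np.abs(p_new - p)), np.max(np.abs(q_new - q)))
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"STAPLE did not converge in {max_iter} iterations", RuntimeWarning)

    consensus = np.full(union.shape, w_out, dtype=float)
    consensus[box] = W.reshape(tuple(h - l for l, h in zip(lo, hi)))
    fused = BinaryMask(grid=stack.grid, voxels=consensus >= threshold)
    state = StapleState(
        sensitivity=p,
        specificity=q,
        consensus=consensus,
        prevalence=f,
        n_iter=it,
        converged=converged,
    )
    return fused, state
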