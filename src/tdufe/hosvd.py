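"""Tucker decomposition by higher-order SVD (HOSVD).

The decomposition writes a 3-way tensor as

    x_ijk = sum_{l1, l2, l3} G(l1, l2, l3) * U1[i, l1] * U2[j, l2] * U3[k, l3]

where each factor matrix ``Un`` holds the left singular vectors of the mode-n
unfolding of ``x`` and the core tensor ``G`` is the projection of ``x`` onto
the factors. At full rank the decomposition is exact; truncation keeps the
leading singular vectors of each mode.

Everything here is deterministic: dense LAPACK SVDs (no randomized solver) and
a fixed sign convention, so repeated runs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tensor_io import ExpressionTensor

__all__ = ["HOSVDResult", "unfold", "refold", "hosvd", "reconstruct"]


@dataclass
class HOSVDResult:
    """Core tensor and per-mode factor matrices of a Tucker/HOSVD decomposition.

    ``factors[n]`` is column-orthonormal with shape ``(dim_n, R_{n+1})``;
    ``mode_singular_values[n]`` holds the nonincreasing singular values of the
    mode-(n+1) unfolding, truncated to the retained rank.
    """

    core: np.ndarray
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]
    mode_singular_values: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def ranks(self) -> tuple[int, int, int]:
        return self.core.shape  # type: ignore[return-value]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "core.npy", self.core)
        for n, (u, s) in enumerate(zip(self.factors, self.mode_singular_values), start=1):
            np.save(directory / f"factor_mode{n}.npy", u)
            np.save(directory / f"singular_values_mode{n}.npy", s)
        meta = {
            "ranks": list(self.ranks),
            "factor_shapes": [list(u.shape) for u in self.factors],
            "sign_convention": "largest-abs-entry-positive",
        }
        (directory / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "HOSVDResult":
        directory = Path(directory)
        core = np.load(directory / "core.npy")
        factors = tuple(np.load(directory / f"factor_mode{n}.npy") for n in (1, 2, 3))
        svals = tuple(np.load(directory / f"singular_values_mode{n}.npy") for n in (1, 2, 3))
        return cls(core, factors, svals)  # type: ignore[arg-type]


def _as_array(t: ExpressionTensor | np.ndarray) -> np.ndarray:
    x = t.values if isinstance(t, ExpressionTensor) else np.asarray(t, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-way tensor")
    return x


def unfold(t: ExpressionTensor | np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization (modes numbered 1..3).

    Rows are indexed by the chosen mode; columns run over the remaining modes
    in increasing mode order with the last of them varying fastest (C order).
    For mode 1 of an ``(N, M, K)`` tensor, column ``j*K + k`` is ``(j, k)``.
    """
    x = _as_array(t)
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axis = mode - 1
    return np.moveaxis(x, axis, 0).reshape(x.shape[axis], -1)


def refold(matrix: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: ``refold(unfold(x, m), m, x.shape) == x``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axis = mode - 1
    rest = [shape[a] for a in range(3) if a != axis]
    return np.moveaxis(np.asarray(matrix).reshape(shape[axis], *rest), 0, axis)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    # Each column flipped so its largest-magnitude entry is positive (first such
    # entry on ties); SVD signs are otherwise implementation-dependent.
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def hosvd(
    t: ExpressionTensor | np.ndarray,
    ranks: tuple[int, int, int] | None = None,
) -> HOSVDResult:
    """Higher-order SVD of a 3-way tensor.

    Factor ``Un`` holds the leading left singular vectors of the mode-n
    unfolding; the default rank per mode is the full numerical rank bound
    ``min(dim_n, prod(other dims))``, so for a tall gene mode only the columns
    the method can ever use are computed (the mode-1 unfolding of a
    66,766 × 8 × 2 tensor has rank at most 16). The core is
    ``x ×1 U1ᵀ ×2 U2ᵀ ×3 U3ᵀ``.
    """
    x = _as_array(t)
    if not np.isfinite(x).all():
        raise ValueError("tensor contains NaN or Inf")
    full = tuple(
        min(x.shape[a], x.shape[(a + 1) % 3] * x.shape[(a + 2) % 3]) for a in range(3)
    )
    if ranks is None:
        ranks = full  # type: ignore[assignment]
    else:
        ranks = tuple(min(int(r), f) for r, f in zip(ranks, full))  # type: ignore[assignment]
        if any(r < 1 for r in ranks):
            raise ValueError("ranks must be >= 1")

    factors: list[np.ndarray] = []
    svals: list[np.ndarray] = []
    for mode in (1, 2, 3):
        a = unfold(x, mode)
        try:
            u, s, _ = np.linalg.svd(a, full_matrices=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover - LAPACK failure
            raise np.linalg.LinAlgError(f"SVD failed on mode-{mode} unfolding: {err}") from err
        r = ranks[mode - 1]
        factors.append(_fix_signs(u[:, :r]))
        svals.append(s[:r])

    core = np.einsum("ijk,ia,jb,kc->abc", x, *factors, optimize=True)
    return HOSVDResult(core, tuple(factors), tuple(svals))  # type: ignore[arg-type]


def reconstruct(r: HOSVDResult) -> np.ndarray:
    """Evaluate the Tucker triple sum by multilinear multiplication."""
    u1, u2, u3 = r.factors
    if r.core.shape != (u1.shape[1], u2.shape[1], u3.shape[1]):
        raise ValueError("core shape inconsistent with factor ranks")
    return np.einsum("abc,ia,jb,kc->ijk", r.core, u1, u2, u3, optimize=True)
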