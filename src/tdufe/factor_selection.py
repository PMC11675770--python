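"""Select which singular-vector triple (l1, l2, l3) carries the signal of interest.

The sample-mode choices encode the study design: the replicate-mode vector
``u_l2`` should be constant across replicates (replicates measure the same
thing), and the slice-mode vector ``u_l3`` should take opposite signs on the
two slice groups (the contrast between e.g. two cell lines). Given (l2, l3),
the gene-mode vector ``u_l1`` is the one whose core weight ``|G(l1, l2, l3)|``
is largest.

Selection is deterministic; a manual override bypasses all scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hosvd import HOSVDResult

__all__ = [
    "FactorChoice",
    "select_constant_vector",
    "select_contrast_vector",
    "select_feature_vector",
    "choose_factors",
    "groups_from_labels",
]


@dataclass
class FactorChoice:
    """Chosen factor-column indices plus per-candidate diagnostics.

    ``constancy_scores[c]`` is sd/|mean| of column ``c`` of the replicate-mode
    factor (lower = flatter; +inf when the mean is exactly zero).
    ``contrast_scores[c]`` is |mean(group A) − mean(group B)| of column ``c``
    of the slice-mode factor; ``contrast_eligible`` marks opposite-signed
    group means. ``core_magnitudes[c]`` is ``|G(c, l2, l3)|``.
    """

    l1: int
    l2: int
    l3: int
    mode: str = "auto"
    constancy_scores: np.ndarray | None = None
    contrast_scores: np.ndarray | None = None
    contrast_eligible: np.ndarray | None = None
    core_magnitudes: np.ndarray | None = None


def select_constant_vector(u2: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick the replicate-mode column flattest across replicates.

    The score is the coefficient of variation sd(u)/|mean(u)|: orthonormal
    columns all share the same norm, so sd alone cannot separate "flat" from
    "small", while the CV is zero exactly for a constant column. A column with
    mean exactly zero scores +inf and is never chosen unless every column does.
    Ties break to the lowest index.
    """
    u2 = np.atleast_2d(np.asarray(u2, dtype=float))
    if u2.shape[1] < 1:
        raise ValueError("factor matrix has no columns")
    means = u2.mean(axis=0)
    sds = u2.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(means == 0, np.inf, sds / np.abs(means))
    return int(np.argmin(scores)), scores


def groups_from_labels(
    slice_labels: Sequence[str], partition: str
) -> tuple[list[int], list[int]]:
    """Parse a ``"A101D:MeWo"``-style partition string into two index groups.

    Each side of the colon is a comma-separated list of slice labels.
    """
    left, _, right = partition.partition(":")
    if not right:
        raise ValueError("partition must be 'labelA[,..]:labelB[,..]'")
    idx = {label: i for i, label in enumerate(slice_labels)}
    try:
        a = [idx[s.strip()] for s in left.split(",")]
        b = [idx[s.strip()] for s in right.split(",")]
    except KeyError as err:
        raise ValueError(f"unknown slice label {err.args[0]!r}") from err
    if set(a) & set(b):
        raise ValueError("groups overlap")
    return a, b


def select_contrast_vector(
    u3: np.ndarray,
    groups: tuple[Sequence[int], Sequence[int]] | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the slice-mode column with opposite-signed means on the two groups.

    Among eligible columns (group means of opposite sign) the one maximizing
    |mean(A) − mean(B)| wins, ties to the lowest index. If no column is
    eligible an error suggests manual selection — the decomposition then has
    no between-group contrast to exploit.
    """
    scores, eligible = _contrast_scores(u3, groups)
    if not eligible.any():
        raise ValueError(
            "no slice-mode column has opposite-signed group means; "
            "select the contrast vector manually"
        )
    masked = np.where(eligible, scores, -np.inf)
    return int(np.argmax(masked)), scores


def _contrast_scores(
    u3: np.ndarray,
    groups: tuple[Sequence[int], Sequence[int]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    u3 = np.atleast_2d(np.asarray(u3, dtype=float))
    if groups is None:
        if u3.shape[0] != 2:
            raise ValueError("groups required when the slice mode has K != 2")
        groups = ([0], [1])
    ga, gb = (list(groups[0]), list(groups[1]))
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    mean_a = u3[ga].mean(axis=0)
    mean_b = u3[gb].mean(axis=0)
    return np.abs(mean_a - mean_b), mean_a * mean_b < 0


def select_feature_vector(core: np.ndarray, l2: int, l3: int) -> tuple[int, np.ndarray]:
    """Pick the gene-mode index l1 maximizing the core weight |G(l1, l2, l3)|."""
    core = np.asarray(core, dtype=float)
    g = np.abs(core[:, l2, l3])
    if not g.any():
        raise ValueError(f"core slice G(:, {l2}, {l3}) is all zeros")
    return int(np.argmax(g)), g


def choose_factors(
    result: HOSVDResult,
    groups: tuple[Sequence[int], Sequence[int]] | None = None,
    manual: tuple[int | None, int | None, int | None] | None = None,
) -> FactorChoice:
    """Run the full automatic selection, honoring any manual overrides.

    ``manual`` gives explicit ``(l1, l2, l3)`` indices; ``None`` entries fall
    back to the automatic criterion for that mode.
    """
    _, u2, u3 = result.factors
    man1, man2, man3 = manual if manual is not None else (None, None, None)

    constancy = contrast = eligible = None
    if man2 is None:
        l2, constancy = select_constant_vector(u2)
    else:
        l2 = _check_index(man2, u2.shape[1], "l2")
    if man3 is None:
        l3, contrast = select_contrast_vector(u3, groups)
        _, eligible = _contrast_scores(u3, groups)
    else:
        l3 = _check_index(man3, u3.shape[1], "l3")
    if man1 is None:
        l1, magnitudes = select_feature_vector(result.core, l2, l3)
    else:
        l1 = _check_index(man1, result.core.shape[0], "l1")
        magnitudes = np.abs(result.core[:, l2, l3])

    mode = "manual" if manual is not None and any(m is not None for m in manual) else "auto"
    return FactorChoice(
        l1=l1,
        l2=l2,
        l3=l3,
        mode=mode,
        constancy_scores=constancy,
        contrast_scores=contrast,
        contrast_eligible=eligible,
        core_magnitudes=magnitudes,
    )


def _check_index(value: int, bound: int, name: str) -> int:
    value = int(value)
    if not 0 <= value < bound:
        raise IndexError(f"{name}={value} outside [0, {bound})")
    return value
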