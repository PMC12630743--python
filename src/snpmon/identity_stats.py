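"""Probability-of-identity statistics for sizing an individual-ID marker panel.

PID is the probability that two individuals drawn at random from a
population in Hardy-Weinberg equilibrium carry an identical genotype at a
locus; PIDsib is the same probability for a pair of full siblings and is the
conservative choice when related animals may occur in the data, as they do
in any wolf pack.  Multi-locus values multiply across unlinked loci, and the
number of markers needed is the shortest prefix (most informative first)
whose cumulative product drops below a target such as 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: returned by markers_needed when the threshold is never reached
NOT_REACHED = -1


def _check_simplex(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("allele frequencies must be a non-empty 1-D vector")
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError(f"allele frequencies must be a probability simplex: {p}")
    return p


def pid_locus(allele_freqs: Sequence[float]) -> float:
    """Probability two random HWE individuals share a genotype at one locus.

    PID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2, valid for any allele count.
    """
    p = _check_simplex(allele_freqs)
    hom = float(np.sum(p**4))
    s2 = float(np.sum(p**2))
    # sum_{i<j} (2 p_i p_j)^2 = 2 * [ (sum p_i^2)^2 - sum p_i^4 ]
    het = 2.0 * (s2**2 - float(np.sum(p**4)))
    return hom + het


def pid_sib_locus(allele_freqs: Sequence[float]) -> float:
    """Probability two full siblings share a genotype at one locus.

    PIDsib = 0.25 + 0.5*sum p_i^2 + 0.5*(sum p_i^2)^2 - 0.25*sum p_i^4.
    """
    p = _check_simplex(allele_freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


def cumulative_products(per_locus_values: Sequence[float]) -> np.ndarray:
    """Cumulative multi-locus products in most-informative-first order."""
    v = np.sort(np.asarray(per_locus_values, dtype=float))
    if np.any((v <= 0) | (v > 1)):
        raise ValueError("per-locus identity values must lie in (0, 1]")
    return np.cumprod(v)


def markers_needed(per_locus_values: Sequence[float], threshold: float) -> int:
    """Smallest number of loci whose combined identity probability < threshold.

    Loci are taken in ascending per-locus order (most informative first);
    returns NOT_REACHED when even the full panel stays above the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(per_locus_values) == 0:
        return NOT_REACHED
    cum = cumulative_products(per_locus_values)
    below = np.nonzero(cum < threshold)[0]
    return int(below[0]) + 1 if below.size else NOT_REACHED


@dataclass
class PIDResult:
    """Per-locus and cumulative identity power of a marker set."""

    marker_ids: list[str]
    pid: np.ndarray
    pid_sib: np.ndarray
    n_markers_pid: int
    n_markers_pidsib: int
    threshold: float


def panel_identity_power(
    marker_freqs: dict[str, Sequence[float]], threshold: float = 1e-4
) -> PIDResult:
    """PID/PIDsib per marker plus markers-needed counts for a whole panel."""
    ids = list(marker_freqs)
    pid = np.array([pid_locus(marker_freqs[m]) for m in ids])
    sib = np.array([pid_sib_locus(marker_freqs[m]) for m in ids])
    return PIDResult(
        marker_ids=ids,
        pid=pid,
        pid_sib=sib,
        n_markers_pid=markers_needed(pid, threshold),
        n_markers_pidsib=markers_needed(sib, threshold),
        threshold=threshold,
    )
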