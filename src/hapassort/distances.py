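"""Pairwise genetic distances (p, JC69, TN93) and divergence summaries.

All distances use pairwise deletion: an alignment column is excluded
from a pair's comparison when either symbol is a gap, ``N``, or an
IUPAC ambiguity code.  Saturated or undefined model corrections are
reported as ``+inf`` with an explicit flag, never as silent NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import Alignment

log = logging.getLogger(__name__)

MODELS = ("p", "jc69", "tn93")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceError(ValueError):
    pass


class NoOverlapError(DistanceError):
    """A sequence pair shares no comparable (unambiguous) columns."""


def encode(alignment: Alignment) -> np.ndarray:
    """Encode an alignment as uint8 codes: A,C,G,T -> 0..3, everything else 255."""
    mat = alignment.matrix
    out = np.full(mat.shape, 255, dtype=np.uint8)
    for sym, code in _CODE.items():
        out[mat == sym] = code
    return out


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for sym, code in _CODE.items():
        out[arr == ord(sym)] = code
    return out


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected proportion of differing sites, with pairwise deletion.

    Returns ``(proportion, n_compared_sites)``.
    """
    if len(a) != len(b):
        raise DistanceError("sequences differ in length")
    xa, xb = _encode_seq(a), _encode_seq(b)
    return _p_from_codes(xa, xb)


def _p_from_codes(xa: np.ndarray, xb: np.ndarray) -> tuple[float, int]:
    valid = (xa != 255) & (xb != 255)
    m = int(valid.sum())
    if m == 0:
        raise NoOverlapError("no comparable sites between the two sequences")
    diff = int((xa[valid] != xb[valid]).sum())
    return diff / m, m


def jc69(p: float) -> float:
    """Jukes-Cantor correction -(3/4)ln(1 - 4p/3); +inf when saturated (p >= 3/4)."""
    if p < 0:
        raise DistanceError("p-distance must be nonnegative")
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def tn93(a: str, b: str) -> tuple[float, bool]:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Uses observed purine-transition (A<->G) and pyrimidine-transition
    (C<->T) proportions, the transversion proportion, and base
    frequencies averaged over the two sequences.  Returns
    ``(distance, defined)``; when a frequency class is empty or a log
    argument is nonpositive the JC69 fallback is returned with
    ``defined=False`` and a warning.
    """
    if len(a) != len(b):
        raise DistanceError("sequences differ in length")
    xa, xb = _encode_seq(a), _encode_seq(b)
    return _tn93_from_codes(xa, xb)


def _tn93_from_codes(xa: np.ndarray, xb: np.ndarray) -> tuple[float, bool]:
    valid = (xa != 255) & (xb != 255)
    m = int(valid.sum())
    if m == 0:
        raise NoOverlapError("no comparable sites between the two sequences")
    va, vb = xa[valid], xb[valid]

    counts = np.bincount(va, minlength=4) + np.bincount(vb, minlength=4)
    gA, gC, gG, gT = counts / counts.sum()
    gR, gY = gA + gG, gC + gT

    pair = np.minimum(va, vb) * 4 + np.maximum(va, vb)
    P1 = float(np.mean(pair == 0 * 4 + 2))          # A<->G
    P2 = float(np.mean(pair == 1 * 4 + 3))          # C<->T
    diff = float(np.mean(va != vb))
    Q = diff - P1 - P2                               # transversions

    p_obs = diff

    def fallback(reason: str) -> tuple[float, bool]:
        log.warning("TN93 undefined (%s); falling back to JC69", reason)
        return jc69(p_obs), False

    if gA * gG == 0 or gC * gT == 0 or gR * gY == 0:
        if diff == 0:
            # identical sequences: distance is 0 regardless of composition
            return 0.0, True
        return fallback("empty base-frequency class")

    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    w1 = 1.0 - P1 / k1 - Q / (2 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2 * gY)
    w3 = 1.0 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return fallback("log argument <= 0 (saturation)")
    d = (
        -k1 * np.log(w1)
        - k2 * np.log(w2)
        - 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * np.log(w3)
    )
    return float(d), True


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its model tag."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    model: str
    saturated: bool = False

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DistanceError("distance matrix shape mismatch")

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])


def distance_matrix(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """All-pairs distances under the selected model."""
    if model not in MODELS:
        raise DistanceError(f"unknown model {model!r}; choose from {MODELS}")
    if alignment.n_samples < 2:
        raise DistanceError("need at least 2 samples for a distance matrix")
    codes = encode(alignment)
    n = alignment.n_samples
    vals = np.zeros((n, n))
    saturated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                if model == "p":
                    d, _ = _p_from_codes(codes[i], codes[j])
                elif model == "jc69":
                    p, _ = _p_from_codes(codes[i], codes[j])
                    d = jc69(p)
                else:
                    d, _defined = _tn93_from_codes(codes[i], codes[j])
                if not np.isfinite(d):
                    saturated = True
                vals[i, j] = vals[j, i] = d
    return DistanceMatrix(alignment.sample_ids, vals, model, saturated)


def between_group_divergence(
    dm: DistanceMatrix, group1: set[str], group2: set[str]
) -> dict[str, float]:
    """Mean (and min/max) distance over all between-group pairs."""
    if not group1 or not group2:
        raise DistanceError("both groups must be nonempty")
    if group1 & group2:
        raise DistanceError("groups must be disjoint")
    index = {s: i for i, s in enumerate(dm.sample_ids)}
    missing = (group1 | group2) - set(index)
    if missing:
        raise DistanceError(f"ids not in distance matrix: {sorted(missing)}")
    i1 = [index[s] for s in sorted(group1)]
    i2 = [index[s] for s in sorted(group2)]
    block = dm.values[np.ix_(i1, i2)]
    return {
        "mean": float(block.mean()),
        "min": float(block.min()),
        "max": float(block.max()),
        "n_pairs": int(block.size),
    }
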