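"""Physicochemical property response (PR) matrices.

A protein of length N with per-position property values v_1..v_N is encoded
as the symmetric N x N matrix

    PRM(i, j) = v_i + v_j ,

i.e. the outer sum of the property vector with itself.  Matrices above a
configurable side length (default 250) are downscaled by separable bilinear
interpolation so that every protein yields a bounded-size "image" for the
texture-descriptor stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .properties import PropertyTable

__all__ = ["PRMatrix", "SequenceTooLongError", "build_prm", "compress_prm"]

DEFAULT_MAX_SIDE = 250
DEFAULT_MAX_LEN = 5000


class SequenceTooLongError(ValueError):
    """Sequence exceeds the configured maximum length."""


@dataclass
class PRMatrix:
    """Square property-response matrix for one protein.

    Attributes
    ----------
    values
        The (possibly compressed) symmetric matrix.
    source_length
        Original sequence length N.
    compressed
        True if the matrix was resized from its native N x N shape.
    """

    values: np.ndarray
    source_length: int
    compressed: bool = False

    @property
    def side(self) -> int:
        return self.values.shape[0]


def build_prm(
    sequence: str,
    table: PropertyTable,
    max_len: int = DEFAULT_MAX_LEN,
) -> PRMatrix:
    """Build the PR matrix of ``sequence`` under ``table``.

    The sequence is upper-cased before lookup; ambiguous letters are
    resolved by the table's policy.  Sequences longer than ``max_len``
    are rejected (they are expected to be filtered out upstream).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > max_len:
        raise SequenceTooLongError(
            f"sequence length {len(seq)} exceeds max_len={max_len}"
        )
    v = np.asarray(table.vectorize(seq), dtype=float)
    values = v[:, None] + v[None, :]
    return PRMatrix(values=values, source_length=len(seq), compressed=False)


def _resample_positions(n_in: int, n_out: int) -> np.ndarray:
    """Source coordinates of a uniform n_out grid over [0, n_in - 1]."""
    if n_out == 1:
        return np.array([(n_in - 1) / 2.0])
    return np.linspace(0.0, n_in - 1, n_out)


def _resize_1d_weights(n_in: int, n_out: int, method: str):
    pos = _resample_positions(n_in, n_out)
    if method == "nearest":
        idx = np.rint(pos).astype(int)
        return idx, idx, np.zeros_like(pos)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    return lo, hi, frac


def compress_prm(
    prm: PRMatrix,
    max_side: int = DEFAULT_MAX_SIDE,
    method: str = "bilinear",
) -> PRMatrix:
    """Downscale ``prm`` to ``max_side`` x ``max_side`` if it is larger.

    Matrices with side <= ``max_side`` pass through untouched.  Bilinear
    resizing is separable, so symmetry of the input is preserved exactly
    up to floating-point roundoff, and interpolation is convex so the
    value range never widens.  ``method="nearest"`` selects the nearest
    grid point instead.
    """
    if max_side < 2:
        raise ValueError(f"max_side must be >= 2, got {max_side}")
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown compression method {method!r}")
    n = prm.side
    if n <= max_side:
        return prm
    lo, hi, frac = _resize_1d_weights(n, max_side, method)
    v = prm.values
    # rows then columns; identical 1-D weights keep the result symmetric
    rows = v[lo, :] * (1.0 - frac)[:, None] + v[hi, :] * frac[:, None]
    out = rows[:, lo] * (1.0 - frac)[None, :] + rows[:, hi] * frac[None, :]
    return PRMatrix(values=out, source_length=prm.source_length, compressed=True)
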