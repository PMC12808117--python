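"""Dual-tree complex wavelet transform (2-D) built from PyWavelets filter banks.

The transform runs four parallel real 2-D DWTs ("trees"), one for each
combination of a primary (``a``) and a shifted/reversed (``b``) filter tree
along rows and columns:

* level 1 uses an odd-length biorthogonal pair for both trees; tree ``b`` is
  realized by advancing the input one sample along its axis before analysis
  (the classic odd/even sampling construction), giving the two trees
  complementary sampling phases;
* levels >= 2 use an even-length near-symmetric orthonormal filter for tree
  ``a`` and its time-reverse for tree ``b``, which approximates the
  half-sample delay required for the trees to form complex (analytic)
  coefficient pairs.

Complex magnitudes are read off as the root-sum-square of the four trees'
coefficients at a position — the combined energy of the two conjugate complex
subbands — which is approximately shift invariant and is what the fusion rule
ranks.  Each tree is individually perfectly reconstructing (verified under
periodized boundary handling), so the inverse averages the four tree
reconstructions after undoing the level-1 input shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

TREES = ("aa", "ab", "ba", "bb")
DETAIL_KEYS = ("ad", "da", "dd")

_LEVEL1 = pywt.Wavelet("bior2.2")
_QA = pywt.Wavelet("sym4")
_QB = pywt.Wavelet(
    "sym4_reversed",
    filter_bank=[
        _QA.dec_lo[::-1],
        _QA.dec_hi[::-1],
        _QA.rec_lo[::-1],
        _QA.rec_hi[::-1],
    ],
)


def _tree_shift(tree: str) -> tuple[int, int]:
    """Level-1 input advance for a tree: 1 sample along each 'b' axis."""
    return (1 if tree[0] == "b" else 0, 1 if tree[1] == "b" else 0)


def _wavelets(tree: str, level: int) -> tuple[pywt.Wavelet, pywt.Wavelet]:
    if level == 0:
        return (_LEVEL1, _LEVEL1)
    return (
        _QA if tree[0] == "a" else _QB,
        _QA if tree[1] == "a" else _QB,
    )


@dataclass
class DtcwtPyramid:
    """Forward-transform output: per-tree lowpass and per-level details.

    ``details[j][tree][key]`` is the level-``j`` (0 = finest) detail band of
    one tree; keys follow pywt's dwtn naming ('ad', 'da', 'dd').
    """

    shape: tuple[int, int]
    levels: int
    lowpass: dict[str, np.ndarray]
    details: list[dict[str, dict[str, np.ndarray]]]


def _padded_shape(shape: tuple[int, int], levels: int) -> tuple[int, int]:
    m = 1 << levels
    return (-(-shape[0] // m) * m, -(-shape[1] // m) * m)


def dtcwt_forward(image: np.ndarray, levels: int) -> DtcwtPyramid:
    """Decompose a 2-D array to ``levels`` dual-tree levels.

    The input is edge-padded to a multiple of ``2**levels`` so every level
    halves exactly; :func:`dtcwt_inverse` crops back to the original shape.
    """
    if image.ndim != 2:
        raise ValueError("dtcwt_forward expects a single-channel 2-D array")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if (1 << levels) > min(image.shape):
        raise ValueError(
            f"2**levels={1 << levels} exceeds min image dimension {min(image.shape)}"
        )
    shape = image.shape
    ph, pw = _padded_shape(shape, levels)
    padded = np.pad(
        image.astype(np.float64),
        ((0, ph - shape[0]), (0, pw - shape[1])),
        mode="edge",
    )

    lowpass: dict[str, np.ndarray] = {}
    details: list[dict[str, dict[str, np.ndarray]]] = [
        {t: {} for t in TREES} for _ in range(levels)
    ]
    for tree in TREES:
        approx = np.roll(padded, _tree_shift(tree), axis=(0, 1))
        for j in range(levels):
            coeffs = pywt.dwtn(
                approx, wavelet=_wavelets(tree, j), mode="periodization"
            )
            approx = coeffs.pop("aa")
            for key in DETAIL_KEYS:
                details[j][tree][key] = coeffs[key]
        lowpass[tree] = approx
    return DtcwtPyramid(shape=shape, levels=levels, lowpass=lowpass, details=details)


def dtcwt_inverse(pyr: DtcwtPyramid) -> np.ndarray:
    """Invert :func:`dtcwt_forward` by averaging the four tree inverses."""
    out = np.zeros(_padded_shape(pyr.shape, pyr.levels), dtype=np.float64)
    for tree in TREES:
        approx = pyr.lowpass[tree]
        for j in range(pyr.levels - 1, -1, -1):
            coeffs = dict(pyr.details[j][tree])
            coeffs["aa"] = approx
            approx = pywt.idwtn(
                coeffs, wavelet=_wavelets(tree, j), mode="periodization"
            )
        sy, sx = _tree_shift(tree)
        out += np.roll(approx, (-sy, -sx), axis=(0, 1))
    out /= len(TREES)
    return out[: pyr.shape[0], : pyr.shape[1]]


def detail_magnitude(pyr: DtcwtPyramid, level: int, key: str) -> np.ndarray:
    """Root-sum-square complex magnitude of a detail band across the four trees."""
    sq = np.zeros_like(pyr.details[level][TREES[0]][key])
    for tree in TREES:
        sq += pyr.details[level][tree][key] ** 2
    return np.sqrt(sq)
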