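"""Wavelet filter banks for the de-noising pipeline.

Supported families: Daubechies db1-db8 (filters constructed by spectral
factorization of the half-band Daubechies polynomial), the symlet sym5 and
the biorthogonal pair bior5.5 / rbio5.5 (standard published coefficient
tables).

Filter-bank convention follows the common decimated-DWT layout: a quadruple
``(dec_lo, dec_hi, rec_lo, rec_hi)`` with the decomposition low-pass stored
time-reversed relative to the synthesis low-pass, and high-pass filters
obtained by the quadrature-mirror relations

    dec_hi[n] = (-1)**(n + 1) * rec_lo[n]
    rec_hi[n] = (-1)**n       * dec_lo[n]

which hold for the orthogonal and the biorthogonal families alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np

__all__ = ["WaveletSpec", "SUPPORTED_WAVELETS", "daubechies_scaling"]


def daubechies_scaling(order: int) -> np.ndarray:
    """Minimum-phase Daubechies scaling (synthesis low-pass) filter.

    The filter is the spectral factor of the degree-``order`` half-band
    Daubechies polynomial: ``(1+z)^N`` times the product over the roots of
    ``P(y) = sum_k C(N-1+k, k) y^k`` mapped inside the unit circle via
    ``y = (2 - z - 1/z) / 4``.  Normalized so the taps sum to sqrt(2).

    Parameters
    ----------
    order : int
        Number of vanishing moments N, 1 <= N <= 8 supported here
        (the construction itself is generic).
    """
    if order < 1:
        raise ValueError("Daubechies order must be >= 1")
    pcoefs = [comb(order - 1 + k, k) for k in range(order)]
    kept: list[complex] = []
    if order > 1:
        for y in np.roots(pcoefs[::-1]):
            b = 2.0 - 4.0 * y
            disc = np.sqrt(b * b - 4.0 + 0j)
            for z in ((b + disc) / 2.0, (b - disc) / 2.0):
                if abs(z) < 1.0 - 1e-12:
                    kept.append(z)
    h = np.array([1.0 + 0j])
    for _ in range(order):
        h = np.convolve(h, [1.0, 1.0])
    for zk in kept:
        h = np.convolve(h, [1.0, -zk])
    h = np.real(h)
    h *= np.sqrt(2.0) / h.sum()
    return h


# sym5: least-asymmetric orthogonal wavelet, 5 vanishing moments
# (synthesis low-pass, standard table).
_SYM5_REC_LO = np.array(
    [
        0.019538882735286728,
        -0.021101834024758855,
        -0.17532808990845047,
        0.01660210576452232,
        0.6339789634582119,
        0.7234076904024206,
        0.1993975339773936,
        -0.039134249302383094,
        0.029519490925774643,
        0.027333068345077982,
    ]
)

# bior5.5: biorthogonal wavelet, analysis/synthesis pair (standard table,
# zero-padded to a common even length of 12 taps).
_BIOR55_DEC_LO = np.array(
    [
        0.0,
        0.0,
        0.03968708834740544,
        0.007948108637240322,
        -0.05446378846823691,
        0.34560528195603346,
        0.7366601814282105,
        0.34560528195603346,
        -0.05446378846823691,
        0.007948108637240322,
        0.03968708834740544,
        0.0,
    ]
)
_BIOR55_REC_LO = np.array(
    [
        0.013456709459118716,
        -0.002694966880111507,
        -0.13670658466432914,
        -0.09350469740093886,
        0.47680326579848425,
        0.8995061097486484,
        0.47680326579848425,
        -0.09350469740093886,
        -0.13670658466432914,
        -0.002694966880111507,
        0.013456709459118716,
        0.0,
    ]
)


def _qmf_bank(dec_lo: np.ndarray, rec_lo: np.ndarray):
    n = np.arange(len(dec_lo))
    dec_hi = ((-1.0) ** (n + 1)) * rec_lo
    rec_hi = ((-1.0) ** n) * dec_lo
    return dec_lo, dec_hi, rec_lo, rec_hi


@dataclass(frozen=True)
class WaveletSpec:
    """A mother wavelet identified by family and order.

    Attributes
    ----------
    family : str
        One of ``db``, ``sym``, ``bior``, ``rbio``.
    order : str
        Order tag, e.g. ``"2"`` for db2 or ``"5.5"`` for bior5.5.
    """

    family: str
    order: str

    @classmethod
    def from_name(cls, name: str) -> "WaveletSpec":
        """Parse names like ``db2``, ``sym5``, ``bior5.5``, ``rbio5.5``."""
        for fam in ("bior", "rbio", "sym", "db"):
            if name.startswith(fam):
                return cls(fam, name[len(fam):])
        raise ValueError(f"unknown wavelet name: {name!r}")

    @property
    def name(self) -> str:
        return f"{self.family}{self.order}"

    @property
    def orthogonal(self) -> bool:
        return self.family in ("db", "sym")

    def filter_bank(self):
        """Return ``(dec_lo, dec_hi, rec_lo, rec_hi)`` for this wavelet."""
        return _filter_bank(self.family, self.order)


@lru_cache(maxsize=None)
def _filter_bank(family: str, order: str):
    if family == "db":
        n = int(order)
        if not 1 <= n <= 8:
            raise ValueError("db order must be in 1..8")
        rec_lo = daubechies_scaling(n)
        return _qmf_bank(rec_lo[::-1].copy(), rec_lo)
    if family == "sym":
        if order != "5":
            raise ValueError("only sym5 is supported")
        rec_lo = _SYM5_REC_LO
        return _qmf_bank(rec_lo[::-1].copy(), rec_lo)
    if family == "bior":
        if order != "5.5":
            raise ValueError("only bior5.5 is supported")
        return _qmf_bank(_BIOR55_DEC_LO, _BIOR55_REC_LO)
    if family == "rbio":
        if order != "5.5":
            raise ValueError("only rbio5.5 is supported")
        # reverse biorthogonal: analysis and synthesis banks exchanged
        return _qmf_bank(_BIOR55_REC_LO[::-1].copy(), _BIOR55_DEC_LO[::-1].copy())
    raise ValueError(f"unknown wavelet family: {family!r}")


SUPPORTED_WAVELETS = tuple(
    [f"db{n}" for n in range(1, 9)] + ["sym5", "bior5.5", "rbio5.5"]
)
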