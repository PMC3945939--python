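"""Time-reversible nucleotide substitution models: JC69, F81, F84.

Each model is defined by its instantaneous rate matrix Q, scaled so the
expected substitution rate at stationarity is 1 — branch lengths are
then in expected substitutions per site.  Transition probability
matrices P(t) = exp(Qt) come from a spectral decomposition of the
pi-symmetrized rate matrix, so repeated evaluation during branch-length
optimization costs one 4x4 reconstruction.

F84 is the DNAML model family: one extra within-class
(purine/pyrimidine) transition rate controlled by kappa; kappa = 0
reduces F84 to F81, and F81 with uniform frequencies is JC69.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_PURINES = (0, 2)      # A, G
_PYRIMIDINES = (1, 3)  # C, T


class SubstitutionModel:
    """Reversible 4-state model with stationary frequencies ``pi`` and an
    optional F84 transition/transversion parameter ``kappa``."""

    def __init__(self, name: str, base_frequencies, kappa: float = 0.0):
        pi = np.asarray(base_frequencies, dtype=np.float64)
        if pi.shape != (4,):
            raise ValueError("base_frequencies must have 4 entries (A,C,G,T)")
        if (pi <= 0).any():
            raise ValueError("base frequencies must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"base frequencies sum to {pi.sum()}, not 1")
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.name = name
        self.base_frequencies = pi
        self.kappa = float(kappa)

        Q = self._rate_matrix()
        # reversible Q: diag(pi)^(1/2) Q diag(pi)^(-1/2) is symmetric
        sqrt_pi = np.sqrt(pi)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # kill roundoff asymmetry before eigh
        lam, V = np.linalg.eigh(S)
        self._lam = lam
        self._U = V / sqrt_pi[:, None]
        self._Uinv = V.T * sqrt_pi[None, :]

    def _rate_matrix(self) -> np.ndarray:
        pi = self.base_frequencies
        Q = np.zeros((4, 4))
        pur = pi[list(_PURINES)].sum()
        pyr = pi[list(_PYRIMIDINES)].sum()
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                same_class = (i in _PURINES) == (j in _PURINES)
                if same_class and self.kappa > 0:
                    cls = pur if j in _PURINES else pyr
                    rate = pi[j] * (1.0 + self.kappa / cls)
                Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # normalize expected rate to 1
        return Q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); row = ancestral state, column = descendant."""
        P = (self._U * np.exp(self._lam * t)) @ self._Uinv
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def __repr__(self):
        return (f"SubstitutionModel({self.name}, pi={np.round(self.base_frequencies, 4)}"
                + (f", kappa={self.kappa}" if self.name == "F84" else "") + ")")


def jc69() -> SubstitutionModel:
    return SubstitutionModel("JC69", np.full(4, 0.25))


def f81(base_frequencies) -> SubstitutionModel:
    return SubstitutionModel("F81", base_frequencies)


def f84(base_frequencies, kappa: float = 2.0) -> SubstitutionModel:
    return SubstitutionModel("F84", base_frequencies, kappa=kappa)


def make_model(name: str, alignment=None, kappa: float = 2.0) -> SubstitutionModel:
    """Build a model by name; F81/F84 take empirical base frequencies
    counted from the alignment when one is given."""
    name = name.lower()
    if name == "jc69":
        return jc69()
    if name in ("f81", "f84"):
        pi = np.full(4, 0.25) if alignment is None else empirical_frequencies(alignment)
        return f81(pi) if name == "f81" else f84(pi, kappa)
    raise ValueError(f"unknown model {name!r}; choose jc69, f81 or f84")


def empirical_frequencies(alignment) -> np.ndarray:
    """Base composition of an IUPAC alignment: ambiguity codes contribute
    half counts, N contributes nothing; floored to stay positive."""
    from .encode import SYMBOL_BASES

    counts = np.zeros(4)
    for seq in alignment.sequences:
        for ch in seq:
            bases = SYMBOL_BASES[ch]
            if len(bases) == 4:
                continue
            w = 1.0 / len(bases)
            for b in bases:
                counts[BASES.index(b)] += w
    counts = np.maximum(counts, 1e-6)
    return counts / counts.sum()
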