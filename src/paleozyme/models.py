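"""Reversible substitution models for protein (and binary presence/absence) evolution.

A model is defined by a symmetric exchangeability matrix ``S`` and equilibrium
frequencies ``pi``.  The instantaneous rate matrix is ``Q = S @ diag(pi)`` with
the diagonal set so rows sum to zero; for amino-acid models ``Q`` is rescaled so
that one unit of branch length equals one expected substitution per site
(``-sum(pi_i * Q_ii) = 1``).  Transition probabilities ``P(t) = expm(Q t)`` are
computed from the symmetric eigendecomposition, which is exact for reversible
models and cheap to reuse across branches.

Rate heterogeneity across sites uses the discrete-gamma approximation with
equal-probability categories and mean category rates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._modeldata import _JTT_FREQS, _JTT_LOWER, _WAG_FREQS, _WAG_LOWER

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
#: residues treated as fully missing data (alongside the gap character)
MISSING = set("XBZJUO?" + GAP + ".*")


def _expand_lower(lower: list[float], n: int = 20) -> np.ndarray:
    s = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = lower[k]
            k += 1
    assert k == len(lower)
    return s


class SubstitutionModel:
    """Time-reversible CTMC over a finite residue alphabet.

    Parameters
    ----------
    exchangeabilities
        Symmetric non-negative (k, k) matrix; diagonal ignored.
    frequencies
        Equilibrium frequencies, length k, summing to 1.
    alphabet
        Residue letters, one per state.
    gamma_shape
        Optional shape parameter of a mean-one gamma distribution of
        site rates, discretised into ``n_categories`` equal-probability
        categories (mean rate per category).
    normalize
        Rescale Q to one expected event per site per unit branch length
        (standard for amino-acid models; off for the raw-rate binary
        presence/absence model).
    """

    def __init__(
        self,
        exchangeabilities,
        frequencies,
        alphabet: str = AA_ALPHABET,
        gamma_shape: float | None = None,
        n_categories: int = 4,
        normalize: bool = True,
        name: str = "custom",
    ):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        k = len(alphabet)
        if s.shape != (k, k):
            raise ValueError(f"exchangeability matrix must be {k}x{k}")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must be non-negative and sum to 1")
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        pi = pi / pi.sum()
        self.name = name
        self.alphabet = alphabet
        self.frequencies = pi
        self.exchangeabilities = s
        self.gamma_shape = gamma_shape
        self.n_categories = n_categories

        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if normalize:
            rate = -np.sum(pi * np.diag(q))
            q = q / rate
        self.rate_matrix = q

        # symmetric form B = diag(sqrt(pi)) Q diag(1/sqrt(pi)); eigvecs orthonormal
        sq = np.sqrt(pi)
        b = (q * sq[:, np.newaxis]) / sq[np.newaxis, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        self._eigvals = w
        self._left = u.T * sq[np.newaxis, :]          # U^T diag(sqrt(pi))
        self._right = u / sq[:, np.newaxis]           # diag(1/sqrt(pi)) U

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = expm(Q * t * rate); rows sum to 1 for t >= 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = self._right @ (np.exp(self._eigvals * t * rate)[:, np.newaxis] * self._left)
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def rate_categories(self) -> np.ndarray:
        """Mean-one site-rate multipliers (length 1 without gamma)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a, k = self.gamma_shape, self.n_categories
        # equal-probability bins of Gamma(a, scale=1/a); mean rate within each bin
        bounds = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        upper = gammainc(a + 1, bounds[1:] * a)
        lower = gammainc(a + 1, bounds[:-1] * a)
        rates = k * (upper - lower)
        return rates / rates.mean()

    def encode(self, seq: str) -> np.ndarray:
        """Map residues to state indices; missing/gap characters map to -1."""
        idx = {c: i for i, c in enumerate(self.alphabet)}
        return np.array(
            [idx.get(c.upper(), -1) if c.upper() not in MISSING else -1 for c in seq],
            dtype=np.int64,
        )

    def __repr__(self) -> str:  # pragma: no cover
        g = f", gamma={self.gamma_shape}" if self.gamma_shape else ""
        return f"SubstitutionModel({self.name}, {self.n_states} states{g})"


def jtt(gamma_shape: float | None = None, n_categories: int = 4) -> SubstitutionModel:
    """Jones–Taylor–Thornton empirical amino-acid model."""
    return SubstitutionModel(
        _expand_lower(_JTT_LOWER), _JTT_FREQS,
        gamma_shape=gamma_shape, n_categories=n_categories, name="JTT",
    )


def wag(gamma_shape: float | None = None, n_categories: int = 4) -> SubstitutionModel:
    """Whelan-and-Goldman empirical amino-acid model."""
    return SubstitutionModel(
        _expand_lower(_WAG_LOWER), _WAG_FREQS,
        gamma_shape=gamma_shape, n_categories=n_categories, name="WAG",
    )


def presence_absence(gain_loss_rate: float = 1.0) -> SubstitutionModel:
    """Two-state reversible gain/loss model with equal equilibrium (0.5/0.5).

    Off-diagonal rates equal ``gain_loss_rate / 2`` so the total flip rate at
    equilibrium is ``gain_loss_rate`` per unit branch length; used to model
    residue presence/absence for indel reconstruction.  Alphabet: '0' absent,
    '1' present.
    """
    if gain_loss_rate <= 0:
        raise ValueError("gain_loss_rate must be positive")
    s = np.array([[0.0, gain_loss_rate], [gain_loss_rate, 0.0]])
    return SubstitutionModel(
        s, [0.5, 0.5], alphabet="01", normalize=False, name="presence-absence",
    )


def get_model(name: str, gamma_shape: float | None = None) -> SubstitutionModel:
    name = name.lower()
    if name == "jtt":
        return jtt(gamma_shape)
    if name == "wag":
        return wag(gamma_shape)
    raise ValueError(f"unknown model {name!r} (expected 'jtt' or 'wag')")
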