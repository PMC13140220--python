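"""Time-reversible substitution models: GTR (nucleotide), JTT (amino acid), M0 (codon).

All rate matrices are normalized to one expected substitution per site per unit
branch length.  Among-site rate variation uses the discrete gamma with category
means.  Transition matrices come from the symmetric eigendecomposition that
reversibility affords, so they are numerically exact for any branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from itertools import product

import numpy as np
from scipy.special import gammainc

from ._jtt import JTT_FREQS, JTT_ORDER, jtt_exchangeabilities
from .errors import InputError, NumericalError

NUC_STATES = ("A", "C", "G", "T")
AA_STATES = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
_STOPS = {"TAA", "TAG", "TGA"}
CODON_STATES = tuple(
    sorted("".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in _STOPS)
)

_GENETIC_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, _BASES, _BASES)):
    _GENETIC_CODE[_b1 + _b2 + _b3] = _AAS[_i]


def discrete_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Category rates (means of ncat equal-probability bins) for Gamma(alpha, alpha)."""
    if alpha <= 0:
        raise InputError(f"gamma shape must be positive, got {alpha}")
    if ncat < 1:
        raise InputError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    probs = np.arange(1, ncat) / ncat
    bounds = np.concatenate([[0.0], gamma_dist.ppf(probs, alpha, scale=1.0 / alpha), [np.inf]])
    # mean within each bin via the regularized incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1.0, bounds[1:] * alpha)
    lower = gammainc(alpha + 1.0, bounds[:-1] * alpha)
    rates = ncat * (upper - lower)
    rates = rates / rates.mean()
    return np.maximum(rates, 1e-8)  # guard against exact-zero categories at tiny alpha


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible CTMC over a finite state space.

    Subclass constructors build the symmetric exchangeability matrix ``S`` and
    stationary distribution ``pi``; ``Q = S @ diag(pi)`` normalized to mean
    rate 1.
    """

    states: tuple[str, ...]
    exchangeabilities: np.ndarray = field(repr=False)
    pi: np.ndarray = field(repr=False)
    kind: str = "generic"

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.exchangeabilities.shape != (n, n):
            raise InputError("exchangeability matrix shape mismatch")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise InputError("exchangeabilities must be symmetric")
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi < 0).any():
            raise InputError("pi must be a probability simplex")

    @property
    def nstates(self) -> int:
        return len(self.states)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q (rows sum to 0, mean rate 1)."""
        q = self.exchangeabilities * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.pi * np.diag(q)).sum()
        if mu <= 0:
            raise NumericalError("degenerate rate matrix")
        return q / mu

    @cached_property
    def _eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # symmetric similarity transform: B = D^{1/2} Q D^{-1/2}
        pi = np.maximum(self.pi, 1e-300)
        d = np.sqrt(pi)
        b = self.rate_matrix * (d[:, None] / d[None, :])
        lam, u = np.linalg.eigh((b + b.T) / 2.0)
        left = u.T * d[None, :]  # rows of U^T D^{1/2}
        right = u / d[:, None]  # D^{-1/2} U
        return lam, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); exact via eigendecomposition, clipped to [0, 1]."""
        if t < 0:
            raise InputError(f"negative branch length {t}")
        lam, right, left = self._eig
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


def gtr(
    rates: np.ndarray | list[float] | None = None,
    pi: np.ndarray | list[float] | None = None,
) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``rates`` are the six exchangeabilities in the order
    AC, AG, AT, CG, CT, GT (GT conventionally 1).  Defaults to Jukes-Cantor.
    """
    rates = np.ones(6) if rates is None else np.asarray(rates, dtype=float)
    pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
    if rates.shape != (6,) or (rates <= 0).any():
        raise InputError("GTR needs 6 positive exchangeabilities")
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for r, (i, j) in zip(rates, pairs):
        s[i, j] = s[j, i] = r
    return SubstitutionModel(states=NUC_STATES, exchangeabilities=s, pi=pi / pi.sum(), kind="gtr")


def jc69() -> SubstitutionModel:
    return gtr()


def hky(kappa: float, pi: np.ndarray | None = None) -> SubstitutionModel:
    return gtr(rates=[1.0, kappa, 1.0, 1.0, kappa, 1.0], pi=pi)


def jtt(pi: np.ndarray | None = None) -> SubstitutionModel:
    """JTT empirical amino-acid model, optionally with observed (+F) frequencies.

    States are alphabetical; the published matrix (ARNDC... order) is permuted
    accordingly.
    """
    order = list(JTT_ORDER)
    perm = [order.index(a) for a in AA_STATES]
    s = jtt_exchangeabilities()[np.ix_(perm, perm)]
    freqs = JTT_FREQS[perm] if pi is None else np.asarray(pi, dtype=float)
    return SubstitutionModel(
        states=AA_STATES, exchangeabilities=s, pi=freqs / freqs.sum(), kind="jtt"
    )


def codon_m0(
    kappa: float = 2.0,
    omega: float = 0.2,
    nt_freqs: np.ndarray | list[float] | None = None,
) -> SubstitutionModel:
    """Goldman-Yang M0 codon model with F1x4 frequencies over 61 sense codons.

    Single-nucleotide changes only; transitions scaled by ``kappa``,
    nonsynonymous changes by ``omega``.
    """
    if kappa <= 0 or omega < 0:
        raise InputError("kappa must be > 0 and omega >= 0")
    ntf = np.full(4, 0.25) if nt_freqs is None else np.asarray(nt_freqs, dtype=float)
    ntf = ntf / ntf.sum()
    nt_idx = {b: i for i, b in enumerate("ACGT")}
    pi = np.array([np.prod([ntf[nt_idx[b]] for b in codon]) for codon in CODON_STATES])
    pi = pi / pi.sum()
    n = len(CODON_STATES)
    s = np.zeros((n, n))
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = CODON_STATES[i], CODON_STATES[j]
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = kappa if tuple(diffs[0]) in transitions else 1.0
            if _GENETIC_CODE[ci] != _GENETIC_CODE[cj]:
                rate *= omega
            s[i, j] = s[j, i] = rate
    return SubstitutionModel(states=CODON_STATES, exchangeabilities=s, pi=pi, kind="codon_m0")


def codon_translation() -> dict[str, str]:
    """Codon -> amino acid for the 61 sense codons (standard code)."""
    return {c: _GENETIC_CODE[c] for c in CODON_STATES}
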