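"""Behavioral signal-detection summaries: hit/false-alarm rates, d′,
criterion, and maximum-likelihood meta-d′.

The type-1 model is equal-variance SDT: evidence x ~ N(±d′/2, 1), a "yes"
report when x exceeds the criterion c, so

    d′ = z(H) − z(FA),    c = −(z(H) + z(FA)) / 2.

meta-d′ asks what type-1 sensitivity an ideal observer would need to
produce the observed confidence-conditional accuracy: confidence criteria
are placed around a scaled type-1 criterion (held at its fitted relative
position c/d′), and meta-d′ together with the type-2 criteria are fitted by
maximizing the multinomial likelihood of the confidence counts conditional
on each (stimulus, response) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.stats import norm

from .containers import LEVELS

__all__ = ["SDTSummary", "sdt_summary", "MetaDPrimeResult", "meta_dprime"]


@dataclass
class SDTSummary:
    """Type-1 signal-detection summary of one subject's condition table."""

    H: float                      # hit rate, boundary-corrected
    FA: float                     # false-alarm rate, boundary-corrected
    dprime: float
    criterion: float              # c = −(z(H) + z(FA))/2
    criterion_relative: float     # c′ = c / d′ (0 where d′ = 0)
    n_signal: int
    n_noise: int
    confidence_counts: np.ndarray  # (stimulus, choice, confidence) 2×2×2

    def to_json_dict(self) -> dict:
        return {
            "H": self.H, "FA": self.FA, "dprime": self.dprime,
            "criterion": self.criterion,
            "criterion_relative": self.criterion_relative,
            "n_signal": self.n_signal, "n_noise": self.n_noise,
            "confidence_counts": self.confidence_counts.tolist(),
        }


def _rate(k: int, n: int) -> float:
    """Proportion with the 1/(2N) boundary correction for 0 and 1."""
    r = k / n
    if r == 0.0:
        return 1.0 / (2 * n)
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def sdt_summary(table: pd.DataFrame) -> SDTSummary:
    """Compute H, FA, d′ and criterion from a condition table.

    ``H = P(yes | signal)`` and ``FA = P(yes | noise)``; extreme rates are
    pulled off the boundary by 1/(2N) so the normal quantiles stay finite.
    Fails if either stimulus class is absent.
    """
    stim = table["stimulus"].to_numpy()
    choice = table["choice"].to_numpy()
    n_signal = int(np.sum(stim == "signal"))
    n_noise = int(np.sum(stim == "noise"))
    if n_signal == 0 or n_noise == 0:
        missing = "signal" if n_signal == 0 else "noise"
        raise ValueError(f"stimulus class {missing!r} absent from the table")
    H = _rate(int(np.sum((stim == "signal") & (choice == "yes"))), n_signal)
    FA = _rate(int(np.sum((stim == "noise") & (choice == "yes"))), n_noise)
    dprime = float(norm.ppf(H) - norm.ppf(FA))
    criterion = float(-(norm.ppf(H) + norm.ppf(FA)) / 2)

    counts = np.zeros((2, 2, 2))
    if "confidence" in table.columns:
        for i, s in enumerate(LEVELS["stimulus"]):
            for j, ch in enumerate(LEVELS["choice"]):
                for k, cf in enumerate(LEVELS["confidence"]):
                    counts[i, j, k] = np.sum(
                        (stim == s) & (choice == ch)
                        & (table["confidence"].to_numpy() == cf)
                    )
    return SDTSummary(
        H=H, FA=FA, dprime=dprime, criterion=criterion,
        criterion_relative=criterion / dprime if dprime != 0 else 0.0,
        n_signal=n_signal, n_noise=n_noise, confidence_counts=counts,
    )


@dataclass
class MetaDPrimeResult:
    meta_dprime: float
    dprime: float
    criterion: float
    c2_yes: float                 # high-confidence criterion, yes side
    c2_no: float                  # high-confidence criterion, no side
    logL: float
    logL_at_dprime: float         # profile likelihood with meta-d′ = d′
    converged: bool


def _type2_negll(
    params: np.ndarray, counts: np.ndarray, c_rel: float
) -> float:
    """Negative log-likelihood of confidence counts given (stim, response).

    ``params = (meta_d, log offset yes, log offset no)``; the meta type-1
    criterion sits at ``c_rel · meta_d`` and the type-2 criteria at
    ``meta_c ± exp(offset)``, which enforces their ordering.
    """
    meta_d, la, lb = params
    meta_c = c_rel * meta_d
    c2_yes = meta_c + np.exp(la)
    c2_no = meta_c - np.exp(lb)
    nll = 0.0
    for i, mu in enumerate((meta_d / 2, -meta_d / 2)):  # signal, noise
        p_yes = norm.sf(meta_c - mu)
        p_no = 1.0 - p_yes
        # confidence-conditional probabilities within each response
        p_hi_yes = norm.sf(c2_yes - mu) / max(p_yes, 1e-12)
        p_hi_no = norm.cdf(c2_no - mu) / max(p_no, 1e-12)
        for p_hi, j in ((p_hi_yes, 0), (p_hi_no, 1)):  # yes, no
            p_hi = np.clip(p_hi, 1e-10, 1 - 1e-10)
            nll -= counts[i, j, 0] * np.log(p_hi)
            nll -= counts[i, j, 1] * np.log(1 - p_hi)
    return nll


def meta_dprime(confidence_counts: np.ndarray) -> MetaDPrimeResult:
    """Maximum-likelihood meta-d′ from a 2×2×2 confidence count table.

    ``confidence_counts[stimulus, choice, confidence]`` uses the canonical
    level order (signal/noise, yes/no, high/low). Cells are padded by
    1/(2·n_ratings) when any type-1 cell is empty. The fit maximizes the
    likelihood of the confidence data conditional on each
    (stimulus, response) cell over meta-d′ and the two type-2 criteria,
    holding the type-1 criterion at its fitted relative position c/d′.
    Raises on non-convergence, with the optimizer's diagnostics.
    """
    counts = np.asarray(confidence_counts, dtype=float)
    if counts.shape != (2, 2, 2):
        raise ValueError("confidence_counts must be 2×2×2")
    type1 = counts.sum(axis=2)
    if np.any(type1 == 0) or np.any(counts == 0):
        counts = counts + 0.25  # 1/(2 · n_ratings), n_ratings = 2
        type1 = counts.sum(axis=2)

    H = type1[0, 0] / type1[0].sum()
    FA = type1[1, 0] / type1[1].sum()
    dprime = float(norm.ppf(H) - norm.ppf(FA))
    criterion = float(-(norm.ppf(H) + norm.ppf(FA)) / 2)
    c_rel = criterion / dprime if dprime != 0 else 0.0

    x0 = np.array([dprime if dprime != 0 else 0.5, np.log(0.5), np.log(0.5)])
    opt = scipy.optimize.minimize(
        _type2_negll, x0, args=(counts, c_rel), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000},
    )
    if not opt.success:
        raise RuntimeError(f"meta-d′ fit did not converge: {opt.message}")

    meta_d, la, lb = opt.x
    meta_c = c_rel * meta_d
    # profile likelihood at meta-d′ = d′ (criteria refitted)
    prof = scipy.optimize.minimize(
        lambda ab: _type2_negll(np.array([dprime, *ab]), counts, c_rel),
        x0[1:], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000},
    )
    return MetaDPrimeResult(
        meta_dprime=float(meta_d),
        dprime=dprime,
        criterion=criterion,
        c2_yes=float(meta_c + np.exp(la)),
        c2_no=float(meta_c - np.exp(lb)),
        logL=-float(opt.fun),
        logL_at_dprime=-float(prof.fun),
        converged=bool(opt.success),
    )
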