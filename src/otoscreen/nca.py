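"""Non-compartmental pharmacokinetic analysis of a concentration profile.

Model-free parameters from a single (typically mean) concentration-time
curve: Cmax and Tmax by argmax, AUC(0-t) by the linear trapezoid rule, the
terminal elimination rate lambda_z by log-linear least squares over an
automatically selected terminal window, and the derived t1/2 = ln2/lambda_z,
AUC(0-inf) = AUC(0-t) + C_last/lambda_z, CL/F = dose/AUC(0-inf) and
Vz/F = (CL/F)/lambda_z. Values below the assay LLOQ are censored first.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .types import ConcTimeProfile, NcaResult

logger = logging.getLogger(__name__)


class TerminalFitError(ValueError):
    """The terminal log-linear fit could not produce a positive lambda_z."""


def lloq_censor(profile: ConcTimeProfile) -> ConcTimeProfile:
    """Censor sub-LLOQ concentrations.

    Values below the LLOQ are set to 0 for AUC purposes; those after the peak
    are additionally flagged unquantifiable so the lambda_z fit ignores them.
    Raises if no value reaches the LLOQ.
    """
    if profile.lloq <= 0:
        raise ValueError("lloq must be > 0")
    conc = profile.concentrations.copy()
    below = conc < profile.lloq
    if below.all():
        raise ValueError("all concentrations are below the LLOQ")
    for i in np.flatnonzero(below):
        logger.info("t=%.3g h: concentration %.3g < LLOQ %.3g censored to 0",
                    profile.times[i], conc[i], profile.lloq)
    conc[below] = 0.0
    return ConcTimeProfile(times=profile.times, concentrations=conc,
                           dose=profile.dose, lloq=profile.lloq,
                           quantifiable=~below)


def auc_trapezoid(times, concentrations) -> float:
    """Linear trapezoidal area under the observed curve."""
    return float(np.trapezoid(np.asarray(concentrations, dtype=float),
                              np.asarray(times, dtype=float)))


def _terminal_window(times, log_conc, candidates) -> tuple[slice, float, float]:
    """Best contiguous >=3-point window ending at the last quantifiable point.

    Selection maximizes the adjusted R^2 of the log-linear fit, the usual
    automatic terminal-phase rule; returns (window indices, slope, adj R^2).
    """
    best = None
    end = candidates[-1]
    for start_pos in range(len(candidates) - 2):
        idx = candidates[start_pos:]
        x = times[idx]
        y = log_conc[idx]
        n = len(idx)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[2] + 1e-12:
            best = (idx, slope, adj)
    assert best is not None and best[0][-1] == end
    return best


def nca(profile: ConcTimeProfile, censor: bool = True) -> NcaResult:
    """Full non-compartmental analysis of one profile.

    Cmax/Tmax take the earliest time on ties. The terminal window is every
    contiguous run of >=3 quantifiable post-Tmax points ending at the last
    quantifiable point; the fit with the best adjusted R^2 wins. Raises
    :class:`TerminalFitError` when fewer than three such points exist or when
    the fitted slope shows no decline (lambda_z <= 0).
    """
    if profile.dose <= 0:
        raise ValueError("dose must be > 0")
    if censor:
        profile = lloq_censor(profile)
    t = profile.times
    c = profile.concentrations
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_0t = auc_trapezoid(t, c)

    quant = profile.quantifiable & (c > 0)
    candidates = np.flatnonzero(quant & (np.arange(len(t)) > i_max))
    if len(candidates) < 3:
        raise TerminalFitError(
            f"need >=3 quantifiable post-Tmax points for lambda_z, "
            f"have {len(candidates)}")
    window, slope, adj_r2 = _terminal_window(t, np.log(np.where(c > 0, c, np.nan)),
                                             candidates)
    lambda_z = -float(slope)
    if lambda_z <= 0:
        raise TerminalFitError("terminal fit shows no decline (lambda_z <= 0)")
    t_half = math.log(2.0) / lambda_z
    c_last = float(c[candidates[-1]])
    auc_inf = auc_0t + c_last / lambda_z
    cl_f = profile.dose / auc_inf
    vz_f = cl_f / lambda_z
    return NcaResult(cmax=cmax, tmax=tmax, auc_0t=auc_0t, auc_inf=auc_inf,
                     lambda_z=lambda_z, t_half=t_half, cl_f=cl_f, vz_f=vz_f,
                     n_lambda_points=len(window), lambda_r2_adj=float(adj_r2))
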