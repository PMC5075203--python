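"""Univariate feature distributions for organelle morphology.

Two families are used throughout the simulator: the gamma distribution
(organelle counts, size ratios, shape ratios, intranuclear positions) and the
heavy-tailed t location-scale distribution (cytoplasmic position features that
pile up just outside the nuclear membrane).  Both can be truncated to a finite
support interval, in which case the density is renormalised over that interval
and sampling is done by inverse-CDF restricted to it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

GAMMA = "gamma"
T_LOCATION_SCALE = "t_location_scale"
FAMILIES = (GAMMA, T_LOCATION_SCALE)

FEATURES = ("count", "position", "minor_axis_ratio", "axes_ratio")
ORGANELLES = ("nucleoli", "golgi", "vesicles")


class DistributionError(ValueError):
    """Invalid distribution parameters or unusable data for a fit."""


def _frozen(family: str, params: tuple[float, ...]):
    if family == GAMMA:
        shape, scale = params
        return stats.gamma(shape, scale=scale)
    if family == T_LOCATION_SCALE:
        loc, scale, dof = params
        return stats.t(dof, loc=loc, scale=scale)
    raise DistributionError(f"unknown family {family!r}")


def _validate(family: str, params: tuple[float, ...]) -> None:
    if family == GAMMA:
        if len(params) != 2:
            raise DistributionError("gamma takes (shape, scale)")
        if params[0] <= 0 or params[1] <= 0:
            raise DistributionError("gamma shape and scale must be positive")
    elif family == T_LOCATION_SCALE:
        if len(params) != 3:
            raise DistributionError("t location-scale takes (loc, scale, dof)")
        if params[1] <= 0 or params[2] <= 0:
            raise DistributionError("t scale and dof must be positive")
    else:
        raise DistributionError(f"unknown family {family!r}")


@dataclass(frozen=True)
class FittedPDF:
    """A named univariate distribution for one organelle feature.

    Parameters are ordered (shape, scale) for gamma and (location, scale,
    degrees of freedom) for t location-scale.  ``support`` truncates the law;
    the density is renormalised so it integrates to 1 over the support.
    """

    organelle: str
    feature: str
    family: str
    params: tuple[float, ...]
    support: tuple[float, float] = (0.0, math.inf)
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        _validate(self.family, self.params)
        lo, hi = self.support
        if not lo < hi:
            raise DistributionError(f"empty support {self.support}")
        if self._mass <= 0:
            raise DistributionError("support carries no probability mass")

    @cached_property
    def _dist(self):
        return _frozen(self.family, self.params)

    @cached_property
    def _cdf_bounds(self) -> tuple[float, float]:
        lo, hi = self.support
        d = self._dist
        return float(d.cdf(lo)), float(d.cdf(hi))

    @property
    def _mass(self) -> float:
        clo, chi = self._cdf_bounds
        return chi - clo

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        out = self._dist.pdf(x) / self._mass
        return np.where((x >= lo) & (x <= hi), out, 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        d = self._dist
        c = (d.cdf(np.clip(x, lo, hi)) - d.cdf(lo)) / self._mass
        return np.clip(c, 0.0, 1.0)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling restricted to the support interval."""
        clo, chi = self._cdf_bounds
        u = rng.uniform(clo, chi, size=size)
        return np.asarray(self._dist.ppf(u), dtype=float)

    def mean(self) -> float:
        lo, hi = self.support
        if math.isinf(hi) and lo <= 0 and self.family == GAMMA:
            return float(self._dist.mean())
        from scipy.integrate import quad

        hi_eff = hi if math.isfinite(hi) else float(self._dist.ppf(1 - 1e-9))
        val, _ = quad(lambda x: x * self.pdf(x), max(lo, 1e-12), hi_eff)
        return float(val)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        lo, hi = self.support
        return {
            "organelle": self.organelle,
            "feature": self.feature,
            "family": self.family,
            "params": list(self.params),
            "support": [lo, None if math.isinf(hi) else hi],
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedPDF":
        lo, hi = d["support"]
        return cls(
            organelle=d["organelle"],
            feature=d["feature"],
            family=d["family"],
            params=tuple(float(p) for p in d["params"]),
            support=(float(lo), math.inf if hi is None else float(hi)),
            log_likelihood=d.get("log_likelihood"),
        )


PDFSet = dict[tuple[str, str], FittedPDF]  # keyed by (organelle, feature)


def save_parameter_file(pdfs: PDFSet, path: str | Path, note: str | None = None) -> None:
    doc: dict = {"pdfs": [p.to_dict() for p in pdfs.values()]}
    if note:
        doc["note"] = note
    Path(path).write_text(json.dumps(doc, indent=1))


def load_parameter_file(path: str | Path) -> PDFSet:
    doc = json.loads(Path(path).read_text())
    out: PDFSet = {}
    for d in doc["pdfs"]:
        p = FittedPDF.from_dict(d)
        out[(p.organelle, p.feature)] = p
    return out


def default_parameter_path() -> Path:
    return Path(__file__).parent / "params" / "default_pdfs.json"


def load_default_pdfs() -> PDFSet:
    return load_parameter_file(default_parameter_path())


# -- maximum-likelihood fitting ---------------------------------------------

def _nll(family: str, params: tuple[float, ...], values: np.ndarray,
         support: tuple[float, float]) -> float:
    try:
        _validate(family, params)
    except DistributionError:
        return np.inf
    d = _frozen(family, params)
    lo, hi = support
    mass = d.cdf(hi) - d.cdf(lo)
    if mass <= 0:
        return np.inf
    with np.errstate(divide="ignore"):
        ll = np.log(d.pdf(values)) - math.log(mass)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-ll.sum())


def fit_pdf(values: Iterable[float], family: str,
            support: tuple[float, float] = (0.0, math.inf),
            organelle: str = "", feature: str = "") -> FittedPDF:
    """Truncation-aware maximum-likelihood fit of one feature distribution.

    The plain scipy MLE provides the starting point; when the support actually
    truncates the law, the truncated negative log-likelihood is re-minimised
    with Nelder-Mead so the renormalisation is accounted for.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise DistributionError("non-finite values passed to fit_pdf")
    if values.size < 20:
        raise DistributionError(
            f"need at least 20 values to fit, got {values.size}")
    lo, hi = support
    if np.any(values < lo) or np.any(values > hi):
        raise DistributionError("values fall outside the stated support")
    if np.ptp(values) == 0:
        raise DistributionError("constant data: degenerate fit")

    if family == GAMMA:
        shape0, _, scale0 = stats.gamma.fit(values, floc=0)
        x0 = np.log([shape0, scale0])

        def unpack(z):
            return (float(np.exp(z[0])), float(np.exp(z[1])))
    elif family == T_LOCATION_SCALE:
        dof0, loc0, scale0 = stats.t.fit(values)
        dof0 = min(max(dof0, 0.5), 200.0)
        x0 = np.array([loc0, np.log(scale0), np.log(dof0)])

        def unpack(z):
            return (float(z[0]), float(np.exp(z[1])), float(np.exp(z[2])))
    else:
        raise DistributionError(f"unknown family {family!r}")

    res = optimize.minimize(
        lambda z: _nll(family, unpack(z), values, support),
        x0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    params = unpack(res.x)
    ll = -_nll(family, params, values, support)
    return FittedPDF(organelle=organelle, feature=feature, family=family,
                     params=params, support=support, log_likelihood=ll)
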