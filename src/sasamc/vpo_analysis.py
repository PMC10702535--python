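"""Vapor-pressure-osmometry analysis.

Converts osmolality tables (experimental or simulated) into residual
osmolalities and caffeine-concentration-dependent salting-out constants:

    ΔOsm(m₂, m₃) = Osm(m₂, m₃) − Osm(m₂, 0) − Osm(0, m₃)
    ΔOsm = (C₁ + C₂·m₂)·m₂·m₃,      k_s(m₂) = C₁ + C₂·m₂

The in-silico path builds the osmolality surface from a fitted activity
model (Gibbs-Duhem water activity) and feeds it through the *same*
residual/fit code as experimental tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as c
from .thermo_kb import ActivityModel, SolutionComposition, osmolality

__all__ = [
    "OsmTable",
    "KsFit",
    "osm_to_ln_a1",
    "ln_a1_to_osm",
    "residual_osmolality",
    "fit_ks",
    "in_silico_vpo",
]

OSM_COLUMNS = ("m2", "m3", "osm", "stderr", "label")


def OsmTable(records=None, **kwargs) -> pd.DataFrame:
    """Normalized osmolality table: columns m2, m3 (mol/kg), osm
    (mol/kg), stderr (mol/kg, may be 0), label (salt identity)."""
    df = pd.DataFrame(records, **kwargs)
    if "stderr" not in df:
        df["stderr"] = 0.0
    if "label" not in df:
        df["label"] = "salt"
    missing = set(OSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"osmolality table missing columns {sorted(missing)}")
    if (df["osm"] < 0).any():
        raise ValueError("osmolality must be nonnegative")
    return df[list(OSM_COLUMNS)]


def osm_to_ln_a1(osm):
    """ln a₁ = −M₁·Osm (M₁ = 0.0180153 kg/mol)."""
    osm = np.asarray(osm, dtype=float)
    if np.any(osm < 0):
        raise ValueError("osmolality must be nonnegative")
    out = -c.M1_WATER * osm
    return float(out) if out.ndim == 0 else out


def ln_a1_to_osm(ln_a1):
    """Inverse of :func:`osm_to_ln_a1`."""
    out = -np.asarray(ln_a1, dtype=float) / c.M1_WATER
    return float(out) if out.ndim == 0 else out


def _binary_interpolator(m, osm, stderr, order):
    """Least-squares polynomial through the origin for a binary
    osmolality curve; returns (value_fn, variance_fn, coverage).

    The variance function is the prediction variance of the weighted
    polynomial fit, x(m)ᵀ·Cov·x(m)."""
    m = np.asarray(m, dtype=float)
    osm = np.asarray(osm, dtype=float)
    stderr = np.asarray(stderr, dtype=float)
    order = min(order, max(len(np.unique(m[m > 0])), 1))
    X = np.column_stack([m**p for p in range(1, order + 1)])
    w = 1.0 / np.where(stderr > 0, stderr, 1.0) ** 2
    sw = np.sqrt(w)
    coefs, *_ = np.linalg.lstsq(X * sw[:, None], osm * sw, rcond=None)
    if np.any(stderr > 0):
        cov = np.linalg.inv((X * sw[:, None]).T @ (X * sw[:, None]))
    else:
        cov = np.zeros((order, order))

    def value(mq):
        mq = np.asarray(mq, dtype=float)
        return sum(coef * mq**p for p, coef in enumerate(coefs, start=1))

    def variance(mq):
        x = np.array([mq**p for p in range(1, order + 1)])
        return float(x @ cov @ x)

    def covariance(mq_i, mq_j):
        xi = np.array([mq_i**p for p in range(1, order + 1)])
        xj = np.array([mq_j**p for p in range(1, order + 1)])
        return float(xi @ cov @ xj)

    value.covariance = covariance
    return value, variance, (float(m.min()), float(m.max()))


def residual_osmolality(table: pd.DataFrame, binary_order: int = 2
                        ) -> pd.DataFrame:
    """Residual osmolality of every ternary row of an osmolality table.

    Binary curves Osm(m₂, 0) and Osm(0, m₃) are smoothed by low-order
    polynomials through the origin (per salt label for the salt curve)
    and interpolated at the ternary compositions — extrapolation beyond
    the binary coverage is refused.  Uncertainties combine the three
    terms in quadrature.
    """
    table = OsmTable(table)
    out_rows = []
    covariances = {}
    caff = table[(table["m3"] == 0) & (table["m2"] > 0)]
    if len(caff) == 0:
        raise ValueError("table has no caffeine binary rows (m3 = 0)")
    caff_fn, caff_var, caff_cov = _binary_interpolator(
        caff["m2"], caff["osm"], caff["stderr"], binary_order)

    for label, sub in table.groupby("label"):
        ternary = sub[(sub["m2"] > 0) & (sub["m3"] > 0)]
        if len(ternary) == 0:
            continue
        salt = table[(table["m2"] == 0) & (table["m3"] > 0)
                     & (table["label"] == label)]
        if len(salt) == 0:
            raise ValueError(f"no salt binary rows for label {label!r}")
        salt_fn, salt_var, salt_cov = _binary_interpolator(
            salt["m3"], salt["osm"], salt["stderr"], binary_order)
        label_rows = []
        for row in ternary.itertuples():
            if not (caff_cov[0] <= row.m2 <= caff_cov[1]):
                raise ValueError(
                    f"m2 = {row.m2} outside caffeine binary coverage "
                    f"{caff_cov}; refusing to extrapolate")
            if not (salt_cov[0] <= row.m3 <= salt_cov[1]):
                raise ValueError(
                    f"m3 = {row.m3} outside salt binary coverage "
                    f"{salt_cov}; refusing to extrapolate")
            delta = row.osm - caff_fn(row.m2) - salt_fn(row.m3)
            var = row.stderr**2 + caff_var(row.m2) + salt_var(row.m3)
            label_rows.append(dict(m2=row.m2, m3=row.m3,
                                   delta_osm=float(delta),
                                   stderr=float(np.sqrt(var)), label=label))
        # full covariance of the label's ΔOsm vector: the shared binary
        # fits correlate every pair of residual points
        k = len(label_rows)
        sigma = np.zeros((k, k))
        for i in range(k):
            sigma[i, i] = ternary["stderr"].iloc[i] ** 2
            for j in range(k):
                sigma[i, j] += caff_fn.covariance(label_rows[i]["m2"],
                                                  label_rows[j]["m2"])
                sigma[i, j] += salt_fn.covariance(label_rows[i]["m3"],
                                                  label_rows[j]["m3"])
        covariances[label] = sigma
        out_rows.extend(label_rows)
    if not out_rows:
        raise ValueError("no ternary rows in the osmolality table")
    out = pd.DataFrame(out_rows)
    out.attrs["covariance"] = covariances
    return out


@dataclass
class KsFit:
    """Fitted ΔOsm = (C₁ + C₂·m₂)·m₂·m₃ with 2σ (95%) confidence
    intervals."""

    C1: float
    C2: float
    C1_ci95: float
    C2_ci95: float
    covariance: np.ndarray
    n_points: int
    label: str = "salt"

    def ks(self, m2):
        """k_s(m₂) = C₁ + C₂·m₂."""
        return self.C1 + self.C2 * np.asarray(m2, dtype=float)

    def ks_ci95(self, m2):
        m2 = np.asarray(m2, dtype=float)
        var = (self.covariance[0, 0] + 2.0 * m2 * self.covariance[0, 1]
               + m2**2 * self.covariance[1, 1])
        return 2.0 * np.sqrt(var)


def fit_ks(delta: pd.DataFrame, drop_lowest_m2: bool = False) -> dict:
    """Weighted fit of residual osmolalities to (C₁ + C₂·m₂)·m₂·m₃,
    grouped by salt label.

    With a single distinct m₂ the C₂ term is unidentifiable and is
    fixed to zero (with a warning).  ``drop_lowest_m2`` excludes the
    noisiest, lowest caffeine concentration from the fit.

    When the residual table carries the full ΔOsm covariance (attached
    by :func:`residual_osmolality`) a generalized least-squares fit is
    used, accounting for the correlations introduced by the shared
    binary-curve fits; otherwise weights fall back to 1/stderr².
    """
    fits = {}
    sigma_by_label = delta.attrs.get("covariance", {})
    for label, sub in delta.groupby("label", sort=False):
        keep = (sub["m2"] > 0) & (sub["m3"] > 0)
        if drop_lowest_m2 and sub["m2"].nunique() > 2:
            keep &= sub["m2"] > sub["m2"].min()
        mask = keep.to_numpy()
        sub = sub[keep]
        if len(sub) == 0:
            continue
        y = sub["delta_osm"].to_numpy()
        x1 = (sub["m2"] * sub["m3"]).to_numpy()
        if sub["m2"].nunique() < 2:
            import warnings

            warnings.warn(f"{label}: single caffeine molality; C2 fixed to 0")
            X = x1[:, None]
        else:
            X = np.column_stack([x1, sub["m2"] * x1])

        sigma = sigma_by_label.get(label)
        if sigma is not None:
            sigma = np.asarray(sigma)[np.ix_(mask, mask)]
        if sigma is not None and np.trace(sigma) > 0:
            # GLS with a small ridge for numerical safety
            ridge = 1e-12 * np.trace(sigma) / len(y)
            Sinv = np.linalg.inv(sigma + ridge * np.eye(len(y)))
            cov = np.linalg.inv(X.T @ Sinv @ X)
            beta = cov @ X.T @ Sinv @ y
        else:
            se = sub["stderr"].to_numpy()
            with np.errstate(divide="ignore"):
                w = np.where(se > 0, 1.0 / np.maximum(se, 1e-300) ** 2, 1.0)
            w = np.where(np.isfinite(w), w, 1.0)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            dof = max(len(y) - X.shape[1], 1)
            resid = (y - X @ beta) * sw
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv((X * sw[:, None]).T @ (X * sw[:, None]))
        if X.shape[1] == 1:
            C1, C2 = float(beta[0]), 0.0
            cov = np.array([[cov[0, 0], 0.0], [0.0, 0.0]])
        else:
            C1, C2 = float(beta[0]), float(beta[1])
        fits[label] = KsFit(C1=C1, C2=C2,
                            C1_ci95=2.0 * float(np.sqrt(cov[0, 0])),
                            C2_ci95=2.0 * float(np.sqrt(cov[1, 1])),
                            covariance=cov, n_points=len(sub), label=label)
    if not fits:
        raise ValueError("no usable ternary records to fit")
    return fits


def in_silico_vpo(model: ActivityModel, m2_grid, m3_grid,
                  label: str = "model", binary_order: int = 3) -> dict:
    """Synthetic osmometry experiment driven by an activity model.

    Builds the Gibbs-Duhem osmolality surface Osm(m₂, m₃) over the
    requested grid (binary slices included automatically), then applies
    the identical residual-osmolality and k_s-fitting path used for
    experimental tables.  For a noiseless model surface the fit returns
    the generating (C₁, C₂).
    """
    m2_grid = np.asarray(m2_grid, dtype=float)
    m3_grid = np.asarray(m3_grid, dtype=float)
    rows = []
    for m2 in np.concatenate([[0.0], m2_grid]):
        for m3 in np.concatenate([[0.0], m3_grid]):
            if m2 == 0 and m3 == 0:
                continue
            osm = osmolality(SolutionComposition(m2, m3), model)
            rows.append(dict(m2=m2, m3=m3, osm=osm, stderr=0.0, label=label))
    table = OsmTable(rows)
    delta = residual_osmolality(table, binary_order=binary_order)
    fits = fit_ks(delta)
    return {"osm_table": table, "delta_osm": delta, "ks_fit": fits[label]}
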