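"""Geographic distances and urban/rural group summaries.

Distances are ellipsoidal geodesics on WGS84 (Vincenty's inverse formula),
accurate to well under a metre at the tens-of-kilometres scale of a
colony network, matching GIS "ellipsoidal" measurement settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SymmetricMatrix, check_shared_labels

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """WGS84 geodesic distance in kilometres (Vincenty inverse).

    Falls back to the antipodal midpoint approximation only if the
    iteration fails to converge, which cannot happen at regional scales.
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    u1 = math.atan((1 - _F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - _F) * math.tan(math.radians(lat2)))
    big_l = math.radians(lon2 - lon1)
    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)

    lam = big_l
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cos_u2 * sin_lam, cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sm = 0.0
        else:
            cos_2sm = cos_sigma - 2.0 * sin_u1 * sin_u2 / cos2_alpha
        c = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = big_l + (1.0 - c) * _F * sin_alpha * (
            sigma
            + c * sin_sigma * (cos_2sm + c * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    u_sq = cos2_alpha * (_A**2 - _B**2) / _B**2
    a_coef = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    b_coef = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        b_coef
        * sin_sigma
        * (
            cos_2sm
            + b_coef
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
                - b_coef
                / 6.0
                * cos_2sm
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sm**2)
            )
        )
    )
    return _B * a_coef * (sigma - delta_sigma) / 1000.0


def geo_distance_matrix(colonies: pd.DataFrame) -> SymmetricMatrix:
    """Pairwise geodesic distances (km) between colonies.

    ``colonies`` needs columns colony_id, lat, lon.  Duplicate coordinates
    are allowed (distance 0).
    """
    lat = colonies["lat"].to_numpy(dtype=float)
    lon = colonies["lon"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    labels = list(colonies["colony_id"])
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_km(lat[i], lon[i], lat[j], lon[j])
            values[i, j] = values[j, i] = d
    return SymmetricMatrix(labels, values, kind="geo_km")


@dataclass
class GroupSummary:
    """Within/between-group distance summary with Welch t-tests.

    ``classes`` maps comparison class ("uu", "rr", "ur") to a dict with
    n_pairs, genetic mean/sd and geographic mean/sd.  ``tests`` maps a
    class pair, e.g. ("uu", "ur"), to Welch t, df and two-sided p computed
    on the genetic distances.
    """

    classes: dict
    tests: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cls, d in self.classes.items():
            rows.append({"comparison": cls, **d})
        return pd.DataFrame(rows)


def _pair_class(groups: dict, a, b) -> str:
    ga, gb = groups[a], groups[b]
    if ga == gb:
        return "uu" if ga == "urban" else "rr"
    return "ur"


def group_summary(
    genetic: SymmetricMatrix, geo: SymmetricMatrix, groups: dict
) -> GroupSummary:
    """Class-wise means/SDs of genetic and geographic distance + Welch t-tests.

    ``groups`` maps colony label -> "urban" | "rural".  SDs use the n-1
    denominator.  t-tests compare genetic distances between classes with
    Welch's unequal-variance statistic; classes with fewer than 2 pairs
    are skipped.
    """
    labels = check_shared_labels(genetic, geo)
    geo = geo.reindex(labels)
    gvec = genetic.condensed()
    dvec = geo.condensed()
    cls = np.array([_pair_class(groups, a, b) for a, b in genetic.pair_labels()])

    classes = {}
    for c in ("uu", "rr", "ur"):
        sel = cls == c
        if not sel.any():
            continue
        classes[c] = {
            "n_pairs": int(sel.sum()),
            "genetic_mean": float(np.mean(gvec[sel])),
            "genetic_sd": float(np.std(gvec[sel], ddof=1)) if sel.sum() > 1 else np.nan,
            "geo_mean_km": float(np.mean(dvec[sel])),
            "geo_sd_km": float(np.std(dvec[sel], ddof=1)) if sel.sum() > 1 else np.nan,
        }

    tests = {}
    names = list(classes)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            xa, xb = gvec[cls == a], gvec[cls == b]
            if len(xa) < 2 or len(xb) < 2:
                continue
            if np.var(xa) == 0 and np.var(xb) == 0 and xa.mean() == xb.mean():
                # degenerate: identical constant samples carry no evidence
                tests[(a, b)] = {"t": 0.0, "df": float(len(xa) + len(xb) - 2), "p": 1.0}
                continue
            res = stats.ttest_ind(xa, xb, equal_var=False)
            tests[(a, b)] = {
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
    return GroupSummary(classes=classes, tests=tests)


def welch_df(var1: float, n1: int, var2: float, n2: int) -> float:
    """Welch-Satterthwaite degrees of freedom for a two-sample comparison."""
    a, b = var1 / n1, var2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
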