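"""Site-by-year observation panels and covariate preparation.

A panel holds the averaged winter counts y (mean of weekly maxima per
site-winter, non-negative with exact zeros), an observation mask encoding
site turnover, three site-level covariates (northing, easting, habitat
coded rural = -1 / suburban-urban = +1) and time-varying covariates
(sparrowhawk count, collared dove count, ground-frost days by default).

The CSV interchange format is a long table with one row per site-year:
``site_id, year, y, northing, easting, habitat, <time-varying...>`` where
an empty ``y`` marks a site-year without an observation.  Covariate values
must be present for every year from a site's first observation onward,
because the standard model propagates expected counts through unobserved
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PanelValidationError

SITE_COVARIATES = ("northing", "easting", "habitat")
DEFAULT_TIME_COVARIATES = ("sparrowhawk", "collared_dove", "frost_days")


@dataclass
class ObservationPanel:
    site_ids: np.ndarray          # (S,) identifiers
    years: np.ndarray             # (T,) calendar years
    y: np.ndarray                 # (S, T) counts, NaN where unobserved
    mask: np.ndarray              # (S, T) bool, True = observed
    x_site: np.ndarray            # (S, 3) northing, easting, habitat
    v_time: np.ndarray            # (S, T, K) time-varying covariates
    time_covariates: tuple = DEFAULT_TIME_COVARIATES
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_site(self) -> int:
        return len(self.site_ids)

    @property
    def n_year(self) -> int:
        return len(self.years)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @property
    def first_t(self) -> np.ndarray:
        """Index of each site's first observed year."""
        return self.mask.argmax(axis=1)

    def validate(self) -> None:
        S, T = self.y.shape
        if self.mask.shape != (S, T) or self.x_site.shape[0] != S:
            raise PanelValidationError("inconsistent panel array shapes")
        if self.v_time.shape[:2] != (S, T):
            raise PanelValidationError("v_time must be site x year x K")
        if self.v_time.shape[2] != len(self.time_covariates):
            raise PanelValidationError("v_time K does not match covariate names")
        # an entirely unobserved panel is legitimate (prior-predictive use);
        # otherwise every site must contribute at least one observed year
        if self.mask.any() and not self.mask.any(axis=1).all():
            bad = self.site_ids[~self.mask.any(axis=1)]
            raise PanelValidationError(f"sites with no observed year: {bad[:5]}")
        yo = self.y[self.mask]
        if np.isnan(yo).any() or (yo < 0).any():
            raise PanelValidationError("observed y must be non-negative and non-missing")
        hab = self.x_site[:, 2]
        if not np.isin(hab, (-1.0, 1.0)).all():
            raise PanelValidationError("habitat must be coded -1 (rural) / +1 (urban)")
        if "frost_days" in self.time_covariates and not self.normalized:
            k = self.time_covariates.index("frost_days")
            fr = self.v_time[:, :, k]
            fr = fr[np.isfinite(fr)]
            if ((fr < 0) | (fr > 183)).any():
                raise PanelValidationError("frost_days outside [0, 183]")

    def observed_values(self) -> np.ndarray:
        return self.y[self.mask]


@dataclass
class ScalingRecord:
    """Per-covariate centre and scale used when normalizing a panel."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def sd(self, name: str) -> float:
        return self.sds.get(name, 1.0)


def normalize_covariates(panel: ObservationPanel) -> tuple[ObservationPanel, ScalingRecord]:
    """Z-score every continuous covariate; leave the habitat factor at +-1.

    Continuous site covariates are standardised across sites; time-varying
    covariates across all site-years from each site's first observation.
    Returns a new panel (raw arrays untouched) plus the record needed to
    back-transform coefficients to per-unit scale.
    """
    record = ScalingRecord()
    x = panel.x_site.copy()
    for j, name in enumerate(SITE_COVARIATES):
        if name == "habitat":
            continue
        col = x[:, j]
        m, s = float(col.mean()), float(col.std())
        if s == 0:
            raise PanelValidationError(f"covariate {name!r} is constant")
        x[:, j] = (col - m) / s
        record.means[name] = m
        record.sds[name] = s

    v = panel.v_time.copy()
    live = np.zeros(panel.mask.shape, dtype=bool)
    ft = panel.first_t
    for i in range(panel.n_site):
        live[i, ft[i]:] = True
    for k, name in enumerate(panel.time_covariates):
        col = v[:, :, k][live]
        m, s = float(col.mean()), float(col.std())
        if s == 0:
            raise PanelValidationError(f"covariate {name!r} is constant")
        v[:, :, k] = (v[:, :, k] - m) / s
        record.means[name] = m
        record.sds[name] = s

    out = replace(panel, x_site=x, v_time=v, normalized=True)
    return out, record


# -- CSV interchange -------------------------------------------------------

def read_panel_csv(path, time_covariates=DEFAULT_TIME_COVARIATES) -> ObservationPanel:
    df = pd.read_csv(path)
    required = ["site_id", "year", "y", *SITE_COVARIATES, *time_covariates]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel CSV missing columns: {missing}")
    sites = np.array(sorted(df["site_id"].unique(), key=str))
    years = np.sort(df["year"].unique())
    S, T = len(sites), len(years)
    si = {s: i for i, s in enumerate(sites)}
    yi = {yr: i for i, yr in enumerate(years)}
    y = np.full((S, T), np.nan)
    mask = np.zeros((S, T), dtype=bool)
    x_site = np.full((S, 3), np.nan)
    v_time = np.full((S, T, len(time_covariates)), np.nan)
    for row in df.itertuples(index=False):
        i, t = si[row.site_id], yi[row.year]
        if not pd.isna(row.y):
            y[i, t] = row.y
            mask[i, t] = True
        x_site[i] = [row.northing, row.easting, row.habitat]
        for k, name in enumerate(time_covariates):
            v_time[i, t, k] = getattr(row, name)
    panel = ObservationPanel(
        site_ids=sites, years=years, y=y, mask=mask, x_site=x_site,
        v_time=v_time, time_covariates=tuple(time_covariates),
    )
    ft = panel.first_t
    for i in range(S):
        if np.isnan(v_time[i, ft[i]:, :]).any():
            raise PanelValidationError(
                f"site {sites[i]!r}: covariates must be present for every year "
                "from its first observation onward"
            )
    return panel


def write_panel_csv(panel: ObservationPanel, path) -> None:
    rows = []
    for i, sid in enumerate(panel.site_ids):
        for t, yr in enumerate(panel.years):
            if t < panel.first_t[i] or not np.isfinite(panel.v_time[i, t]).all():
                continue
            rows.append({
                "site_id": sid,
                "year": yr,
                "y": panel.y[i, t] if panel.mask[i, t] else np.nan,
                "northing": panel.x_site[i, 0],
                "easting": panel.x_site[i, 1],
                "habitat": panel.x_site[i, 2],
                **{name: panel.v_time[i, t, k]
                   for k, name in enumerate(panel.time_covariates)},
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
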