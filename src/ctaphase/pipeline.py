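"""Cohort-level analysis: stratified agreement tables and method comparison.

Takes a per-patient table (estimate volume, final infarct volume, perfusion
core/penumbra, HIR, Miteff collateral grade, TICI reperfusion grade, time
from last-known-well) and produces, for every stratifier (Miteff, HIR
dichotomy, TICI outcome) crossed with every presentation-time window (all,
<6 h, 6-24 h):

- Pearson r and ICC(2,1) with 95% CIs between the estimate and the final
  infarct volume per stratum (strata with fewer than 4 evaluable patients
  are reported with counts but no statistics),
- per-stratum median (IQR) volumes with a Kruskal-Wallis comparison across
  strata for both the estimate and the final infarct volume,
- Bland-Altman (percentile limits) and OLS of the estimate against the
  perfusion core and penumbra volumes per window.

Report generation is a pure function of the input table: the same records
always produce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as agstats

__all__ = [
    "PatientRecord",
    "StratumResult",
    "CellResult",
    "MethodComparison",
    "StratifiedReport",
    "classify_tici",
    "lkw_midpoint",
    "assign_time_window",
    "build_report",
    "records_to_frame",
    "frame_to_records",
]

TICI_FUTILE = ("0", "1", "2a")
TICI_SUCCESSFUL = ("2b", "2c", "3")
WINDOWS = ("all", "<6h", "6-24h")
MIN_STRATUM_N = 4


@dataclass
class PatientRecord:
    """One patient's volumes, collateral and reperfusion status, and timing.

    Volumes in mL; ``hir`` in [0, 1]; ``miteff`` 1 (poor) / 2 (moderate) /
    3 (good); ``tici`` one of 0, 1, 2a, 2b, 2c, 3; ``lkw_to_cta_min`` in
    minutes from last known well to CTA (None if unknown); sleep/wake clock
    times ("HH:MM") are present only for wake-up strokes.
    """

    id: str
    cnn_volume_mL: float
    fiv_mL: float
    core_mL: float
    penumbra_mL: float
    hir: float
    miteff: int
    tici: str
    lkw_to_cta_min: float | None = None
    wake_up: bool = False
    sleep_time: str | None = None
    wake_time: str | None = None

    def __post_init__(self):
        for name in ("cnn_volume_mL", "fiv_mL", "core_mL", "penumbra_mL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.hir <= 1.0):
            raise ValueError("hir must be in [0, 1]")
        if self.miteff not in (1, 2, 3):
            raise ValueError("miteff grade must be 1, 2 or 3")
        if str(self.tici) not in TICI_FUTILE + TICI_SUCCESSFUL:
            raise ValueError(f"unknown TICI grade {self.tici!r}")
        self.tici = str(self.tici)


def classify_tici(tici: str) -> str:
    """Dichotomize a TICI reperfusion grade: 0/1/2a futile, 2b/2c/3 successful."""
    grade = str(tici)
    if grade in TICI_FUTILE:
        return "futile"
    if grade in TICI_SUCCESSFUL:
        return "successful"
    raise ValueError(f"unknown TICI grade {tici!r}")


def _parse_clock(t) -> int:
    """Clock time -> minutes past midnight."""
    if hasattr(t, "hour"):
        return t.hour * 60 + t.minute
    h, m = str(t).split(":")
    h, m = int(h), int(m)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {t!r}")
    return h * 60 + m


def lkw_midpoint(sleep_time, wake_time) -> str:
    """Presumed last-known-well time for wake-up stroke: the clock midpoint
    between going to sleep and waking up, wrapping across midnight.

    Equal sleep and wake times are read as a full 24 h apart.  Returns
    "HH:MM".
    """
    s = _parse_clock(sleep_time)
    w = _parse_clock(wake_time)
    span = (w - s) % 1440
    if span == 0:
        span = 1440
    mid = (s + span / 2.0) % 1440
    return f"{int(mid) // 60:02d}:{int(mid) % 60:02d}"


def assign_time_window(lkw_to_cta_min) -> str:
    """Presentation-time window from minutes since last known well.

    "<6h" for < 360 min; "6-24h" for 360-1440 min inclusive; missing or
    out-of-range values map to "unknown" (excluded from windowed strata but
    counted).  Negative times are an error.
    """
    if lkw_to_cta_min is None or (isinstance(lkw_to_cta_min, float) and np.isnan(lkw_to_cta_min)):
        return "unknown"
    m = float(lkw_to_cta_min)
    if m < 0:
        raise ValueError("time from last known well cannot be negative")
    if m < 360:
        return "<6h"
    if m <= 1440:
        return "6-24h"
    return "unknown"


def records_to_frame(records) -> pd.DataFrame:
    """Cohort table (one row per patient) from PatientRecord objects."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list:
    """PatientRecord objects from a cohort table (validates every row)."""
    records = []
    for _, row in df.iterrows():
        lkw = row.get("lkw_to_cta_min")
        if lkw is not None and pd.isna(lkw):
            lkw = None
        records.append(
            PatientRecord(
                id=str(row["id"]),
                cnn_volume_mL=float(row["cnn_volume_mL"]),
                fiv_mL=float(row["fiv_mL"]),
                core_mL=float(row["core_mL"]),
                penumbra_mL=float(row["penumbra_mL"]),
                hir=float(row["hir"]),
                miteff=int(row["miteff"]),
                tici=str(row["tici"]),
                lkw_to_cta_min=None if lkw is None else float(lkw),
                wake_up=bool(row.get("wake_up", False)),
                sleep_time=None if pd.isna(row.get("sleep_time")) else str(row.get("sleep_time")),
                wake_time=None if pd.isna(row.get("wake_time")) else str(row.get("wake_time")),
            )
        )
    return records


@dataclass
class StratumResult:
    label: str
    n: int
    agreement: agstats.AgreementResult | None
    cnn_median: float | None
    cnn_iqr: tuple | None
    fiv_median: float | None
    fiv_iqr: tuple | None
    note: str | None = None


@dataclass
class CellResult:
    stratifier: str
    window: str
    strata: list
    kw_cnn: agstats.GroupComparison | None
    kw_fiv: agstats.GroupComparison | None
    n_missing_stratifier: int
    notes: list = field(default_factory=list)


@dataclass
class MethodComparison:
    window: str
    reference: str  # "core" | "penumbra"
    bland_altman: agstats.BlandAltman | None
    slope: float | None
    intercept: float | None
    n: int


@dataclass
class StratifiedReport:
    n_total: int
    n_unknown_window: int
    cells: list
    method_comparisons: list
    normality: dict

    def cell(self, stratifier: str, window: str) -> CellResult:
        for c in self.cells:
            if c.stratifier == stratifier and c.window == window:
                return c
        raise KeyError((stratifier, window))

    def stratum(self, stratifier: str, window: str, label: str) -> StratumResult:
        for s in self.cell(stratifier, window).strata:
            if s.label == label:
                return s
        raise KeyError((stratifier, window, label))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_plain(dataclasses.asdict(self)), indent=indent, sort_keys=True)

    def table2_frame(self) -> pd.DataFrame:
        """Correlation table: per window x stratifier x stratum, Pearson and
        ICC with CIs and P-values (long format)."""
        rows = []
        for c in self.cells:
            for s in c.strata:
                a = s.agreement
                rows.append(
                    {
                        "window": c.window,
                        "stratifier": c.stratifier,
                        "stratum": s.label,
                        "n": s.n,
                        "pearson_r": a.r if a else None,
                        "pearson_lo": a.r_ci[0] if a else None,
                        "pearson_hi": a.r_ci[1] if a else None,
                        "pearson_p": a.r_p if a else None,
                        "icc": a.icc if a else None,
                        "icc_lo": a.icc_ci[0] if a else None,
                        "icc_hi": a.icc_ci[1] if a else None,
                        "icc_p": a.icc_p if a else None,
                        "note": s.note,
                    }
                )
        return pd.DataFrame(rows)

    def table3_frame(self) -> pd.DataFrame:
        """Median-volume table: per window x stratifier x stratum, median
        (IQR) of estimate and FIV with the across-strata Kruskal-Wallis P."""
        rows = []
        for c in self.cells:
            for s in c.strata:
                rows.append(
                    {
                        "window": c.window,
                        "stratifier": c.stratifier,
                        "stratum": s.label,
                        "n": s.n,
                        "cnn_median": s.cnn_median,
                        "cnn_q1": s.cnn_iqr[0] if s.cnn_iqr else None,
                        "cnn_q3": s.cnn_iqr[1] if s.cnn_iqr else None,
                        "fiv_median": s.fiv_median,
                        "fiv_q1": s.fiv_iqr[0] if s.fiv_iqr else None,
                        "fiv_q3": s.fiv_iqr[1] if s.fiv_iqr else None,
                        "kw_p_cnn": c.kw_cnn.kw_p if c.kw_cnn else None,
                        "kw_p_fiv": c.kw_fiv.kw_p if c.kw_fiv else None,
                    }
                )
        return pd.DataFrame(rows)

    def figure3_stats(self) -> dict:
        """Bland-Altman + OLS numbers of the estimate vs core and penumbra."""
        out = {}
        for mc in self.method_comparisons:
            key = f"{mc.window}:{mc.reference}"
            out[key] = {
                "n": mc.n,
                "mean_diff": mc.bland_altman.mean_diff if mc.bland_altman else None,
                "p2_5": mc.bland_altman.lo if mc.bland_altman else None,
                "p97_5": mc.bland_altman.hi if mc.bland_altman else None,
                "slope": mc.slope,
                "intercept": mc.intercept,
            }
        return out


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _stratifier_groups(df: pd.DataFrame, stratifier: str) -> tuple:
    """(group labels in display order, per-row group series with NaN for
    missing stratifier values)."""
    if stratifier == "Miteff":
        return ("1", "2", "3"), df["miteff"].map({1: "1", 2: "2", 3: "3"})
    if stratifier == "HIR":
        series = pd.Series(
            np.where(df["hir"] < 0.5, "<0.5", ">=0.5"), index=df.index, dtype=object
        )
        series[df["hir"].isna()] = None
        return ("<0.5", ">=0.5"), series
    if stratifier == "TICI":
        return ("futile", "successful"), df["tici"].map(classify_tici)
    raise ValueError(f"unknown stratifier {stratifier!r}")


def build_report(records, min_stratum_n: int = MIN_STRATUM_N) -> StratifiedReport:
    """Stratified agreement report from a patient cohort.

    ``records`` may be a list of :class:`PatientRecord` or an equivalent
    DataFrame.  Strata smaller than ``min_stratum_n`` are reported with
    counts but flagged not-evaluable rather than silently dropped; records
    missing the active stratifier are excluded from that stratification only
    and tallied.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if len(records) == 0:
            raise ValueError("empty cohort")
        df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty cohort")
    df = df.reset_index(drop=True)
    df["window"] = [assign_time_window(v) for v in df["lkw_to_cta_min"]]

    cells = []
    for stratifier in ("Miteff", "HIR", "TICI"):
        labels, groups = _stratifier_groups(df, stratifier)
        for window in WINDOWS:
            in_window = df["window"].eq(window) if window != "all" else pd.Series(True, index=df.index)
            missing = int((in_window & groups.isna()).sum())
            strata = []
            group_cnn, group_fiv, group_labels = [], [], []
            for label in labels:
                sel = in_window & groups.eq(label)
                sub = df[sel]
                n = len(sub)
                cnn = sub["cnn_volume_mL"].to_numpy(dtype=float)
                fiv = sub["fiv_mL"].to_numpy(dtype=float)
                note = None
                agreement = None
                if n >= min_stratum_n:
                    try:
                        agreement = agstats.agreement(cnn, fiv)
                    except ValueError as exc:
                        note = f"agreement not evaluable: {exc}"
                else:
                    note = f"not evaluable: n={n} < {min_stratum_n}"
                med_c = med_f = iqr_c = iqr_f = None
                if n >= 1:
                    med_c, iqr_c = agstats.median_iqr(cnn)
                    med_f, iqr_f = agstats.median_iqr(fiv)
                    group_cnn.append(cnn)
                    group_fiv.append(fiv)
                    group_labels.append(label)
                strata.append(
                    StratumResult(
                        label=label, n=n, agreement=agreement,
                        cnn_median=med_c, cnn_iqr=iqr_c,
                        fiv_median=med_f, fiv_iqr=iqr_f, note=note,
                    )
                )
            kw_cnn = kw_fiv = None
            notes = []
            if len(group_labels) >= 2:
                for name, data in (("cnn", group_cnn), ("fiv", group_fiv)):
                    try:
                        h, p = agstats.kruskal_wallis(data)
                        gc = agstats.GroupComparison(
                            labels=tuple(group_labels),
                            ns=tuple(len(g) for g in data),
                            medians=tuple(agstats.median_iqr(g)[0] for g in data),
                            iqrs=tuple(agstats.median_iqr(g)[1] for g in data),
                            kw_statistic=h,
                            kw_p=p,
                        )
                    except ValueError as exc:
                        gc = None
                        notes.append(f"Kruskal-Wallis ({name}) not evaluable: {exc}")
                    if name == "cnn":
                        kw_cnn = gc
                    else:
                        kw_fiv = gc
            else:
                notes.append("fewer than two non-empty strata; no group comparison")
            cells.append(
                CellResult(
                    stratifier=stratifier, window=window, strata=strata,
                    kw_cnn=kw_cnn, kw_fiv=kw_fiv,
                    n_missing_stratifier=missing, notes=notes,
                )
            )

    method_comparisons = []
    for window in WINDOWS:
        in_window = df["window"].eq(window) if window != "all" else pd.Series(True, index=df.index)
        sub = df[in_window]
        cnn = sub["cnn_volume_mL"].to_numpy(dtype=float)
        for reference in ("core", "penumbra"):
            ref = sub[f"{reference}_mL"].to_numpy(dtype=float)
            ba = slope = intercept = None
            if len(sub) >= 3:
                ba = agstats.bland_altman(cnn, ref)
            if len(sub) >= 2 and np.ptp(ref) > 0:
                slope, intercept = agstats.ols_fit(ref, cnn)
            method_comparisons.append(
                MethodComparison(
                    window=window, reference=reference,
                    bland_altman=ba, slope=slope, intercept=intercept, n=len(sub),
                )
            )

    normality = {}
    for name in ("cnn_volume_mL", "fiv_mL"):
        vals = df[name].to_numpy(dtype=float)
        if 3 <= len(vals) <= 5000 and np.ptp(vals) > 0:
            p, gate = agstats.shapiro_wilk_gate(vals)
            normality[name] = {"shapiro_p": p, "normal": gate}
        else:
            normality[name] = {"shapiro_p": None, "normal": None}

    return StratifiedReport(
        n_total=len(df),
        n_unknown_window=int(df["window"].eq("unknown").sum()),
        cells=cells,
        method_comparisons=method_comparisons,
        normality=normality,
    )
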