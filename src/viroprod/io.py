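"""Tabular I/O, study bundling, and the end-to-end analysis orchestrator.

CSV is the canonical interchange format.  Incubation files carry one row
per observation (station, zone, treatment, replicate, population, time_h,
abundance_per_ml).  Environmental and cross-study tables may print scaled
columns (e.g. N x 10^5 mL^-1); scale factors live in a sidecar JSON schema
(``<name>.schema.json`` next to ``<name>.csv``) and are expanded on load.
Below-detection markers (``n.d.``, ``nd``, ``<x``) are parsed to NaN and
only substituted at analysis time, so they survive round-tripping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import infection as inf
from . import series as ts
from . import stats as st

__all__ = [
    "AnalysisConfig",
    "StudyBundle",
    "SchemaError",
    "read_incubations_csv",
    "read_incubations_excel",
    "write_incubations_csv",
    "read_env_csv",
    "read_cross_study_csv",
    "load_study",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("viroprod")

INCUBATION_COLUMNS = (
    "station",
    "zone",
    "treatment",
    "replicate",
    "population",
    "time_h",
    "abundance_per_ml",
)

_ND_MARKERS = {"n.d.", "nd", "n.d", "ND", "na", ""}


class SchemaError(ValueError):
    """A file violated the expected layout; message names file/row/column."""


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis, mirrored by CLI flags and config files."""

    burst_size: float = inf.DEFAULT_BURST_SIZE
    nd_policy: str = "zero"
    n_perm: int = 10_000
    seed: int = 0
    exclude_env: tuple[str, ...] = ("NO3",)
    exact_spearman: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "exclude_env" in data:
            data["exclude_env"] = tuple(data["exclude_env"])
        return cls(**data)


@dataclass
class StudyBundle:
    """Everything one study provides: environment, incubations, compilation."""

    env_table: list[st.EnvSample] = field(default_factory=list)
    incubations: list[ts.IncubationSeries] = field(default_factory=list)
    cross_study_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.env_table and self.incubations:
            known = {(e.station, e.zone) for e in self.env_table}
            for s in self.incubations:
                if (s.station, s.zone) not in known:
                    raise SchemaError(
                        f"incubation references unknown sample "
                        f"{(s.station, s.zone)}; known: {sorted(known)}"
                    )

    def env_for(self, station: str, zone: str) -> st.EnvSample | None:
        for e in self.env_table:
            if e.station == station and e.zone == zone:
                return e
        return None


def _parse_value(raw) -> float:
    """Parse a table cell; below-detection markers and '<x' become NaN."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s.lower() in _ND_MARKERS:
        return np.nan
    if s.startswith("<"):
        return np.nan
    return float(s)


def _sidecar_scales(path: Path) -> dict[str, float]:
    sidecar = path.parent / (path.stem + ".schema.json")
    if sidecar.exists():
        return {k: float(v) for k, v in json.loads(sidecar.read_text())["scales"].items()}
    return {}


def read_env_csv(path: str | Path) -> pd.DataFrame:
    """Read an environmental/abundance table; expand sidecar column scales."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise SchemaError(f"{path}: file has no data rows")
    out = pd.DataFrame()
    for col in df.columns:
        if col in ("station", "zone", "study", "bs_method"):
            out[col] = df[col].astype(str)
        else:
            try:
                out[col] = [_parse_value(v) for v in df[col]]
            except ValueError as exc:
                raise SchemaError(f"{path}: column {col!r}: {exc}") from exc
    for col, scale in _sidecar_scales(path).items():
        if col in out.columns:
            out[col] = out[col] * scale
    return out


def read_cross_study_csv(path: str | Path, tolerance: float = 0.05) -> pd.DataFrame:
    """Read a cross-study compilation and verify its internal identities.

    Missing VPR/VTT/VT entries are recomputed as VPR = VA/PA,
    VTT = VA/VP/24 (days), VT = 1/VTT; provided entries are checked against
    the recomputation within ``tolerance`` (relative).
    """
    df = read_env_csv(path)
    required = {"prok_abundance", "viral_abundance", "vp"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    va, pa, vp = df["viral_abundance"], df["prok_abundance"], df["vp"]
    recomputed = {
        "vpr": va / pa,
        "vtt_d": va / vp / 24.0,
    }
    recomputed["vt_per_d"] = 1.0 / recomputed["vtt_d"]
    for col, calc in recomputed.items():
        if col not in df.columns:
            df[col] = calc
            continue
        given = df[col]
        both = given.notna() & calc.notna()
        rel = np.abs(given[both] - calc[both]) / np.abs(calc[both])
        bad = rel[rel > tolerance]
        if len(bad):
            row = int(bad.index[0])
            raise SchemaError(
                f"{path}: row {row}, column {col!r}: value "
                f"{given[row]:.4g} deviates {rel[row]:.1%} from recomputed "
                f"{calc[row]:.4g} (> {tolerance:.0%})"
            )
        df[col] = given.fillna(calc)
    return df


def read_incubations_csv(path: str | Path) -> list[ts.IncubationSeries]:
    """Read incubation observations into IncubationSeries records.

    Raises
    ------
    SchemaError
        Naming file, row, and column on any violation, including duplicated
        (station, zone, treatment, replicate, population, time) keys.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _frame_to_series(df, origin=str(path))


def read_incubations_excel(
    path: str | Path, sheet: str | int = 0, column_map: Mapping[str, str] | None = None
) -> list[ts.IncubationSeries]:
    """Read an Excel workbook in the same logical layout (optional path).

    ``column_map`` renames workbook columns onto the canonical schema.
    Requires the ``excel`` extra (openpyxl).
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return _frame_to_series(df, origin=str(path))


def _frame_to_series(df: pd.DataFrame, origin: str) -> list[ts.IncubationSeries]:
    missing = set(INCUBATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{origin}: missing columns {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{origin}: file has no data rows")
    key_cols = ["station", "zone", "treatment", "replicate", "population"]
    dup = df.duplicated(subset=key_cols + ["time_h"])
    if dup.any():
        row = int(df.index[dup][0]) + 2  # 1-based incl. header
        raise SchemaError(f"{origin}: row {row}: duplicate observation key")
    out = []
    for key, grp in df.groupby(key_cols, sort=True):
        grp = grp.sort_values("time_h")
        try:
            out.append(
                ts.IncubationSeries(
                    station=str(key[0]),
                    zone=str(key[1]),
                    treatment=str(key[2]),
                    replicate=int(key[3]),
                    population=str(key[4]),
                    times=tuple(float(t) for t in grp["time_h"]),
                    abundances=tuple(float(a) for a in grp["abundance_per_ml"]),
                )
            )
        except (ts.InvalidSeriesError, ValueError) as exc:
            raise SchemaError(f"{origin}: series {key}: {exc}") from exc
    return out


def incubations_to_frame(series: Iterable[ts.IncubationSeries]) -> pd.DataFrame:
    rows = [
        {
            "station": s.station,
            "zone": s.zone,
            "treatment": s.treatment,
            "replicate": s.replicate,
            "population": s.population,
            "time_h": t,
            "abundance_per_ml": a,
        }
        for s in series
        for t, a in zip(s.times, s.abundances)
    ]
    return pd.DataFrame(rows, columns=list(INCUBATION_COLUMNS))


def write_incubations_csv(series: Iterable[ts.IncubationSeries], path: str | Path) -> None:
    incubations_to_frame(series).to_csv(path, index=False)


def load_study(
    incubations: str | Path | None = None,
    env: str | Path | None = None,
    cross_study: str | Path | None = None,
) -> StudyBundle:
    """Assemble a StudyBundle from CSV paths (each optional)."""
    env_samples: list[st.EnvSample] = []
    if env is not None:
        df = read_env_csv(env)
        for _, row in df.iterrows():
            env_samples.append(
                st.EnvSample(
                    station=row.get("station", ""),
                    zone=row.get("zone", ""),
                    depth=float(row["depth_m"]),
                    temperature=float(row["temperature_c"]),
                    salinity=float(row["salinity"]),
                    turbidity=float(row["turbidity_ntu"]),
                    PO4=_none_if_nan(row.get("po4_um")),
                    NO2=_none_if_nan(row.get("no2_um")),
                    NO3=_none_if_nan(row.get("no3_um")),
                    NH4=_none_if_nan(row.get("nh4_um")),
                    O2=_none_if_nan(row.get("o2_um")),
                    H2S=_none_if_nan(row.get("h2s_um")),
                    prok_abundance=_none_if_nan(row.get("prok_avg")),
                    viral_abundance=_none_if_nan(row.get("virus_avg")),
                    vpr=_none_if_nan(row.get("vpr")),
                )
            )
    incs = read_incubations_csv(incubations) if incubations is not None else []
    cross = read_cross_study_csv(cross_study) if cross_study is not None else None
    return StudyBundle(
        env_table=env_samples, incubations=incs, cross_study_table=cross
    )


def _none_if_nan(v) -> float | None:
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


# ---------------------------------------------------------------------------
# orchestration


def _summary_dict(s: ts.DuplicateSummary) -> dict:
    return {"average": s.average, "low": s.low, "high": s.high}


def _group_incubations(
    incubations: Sequence[ts.IncubationSeries],
) -> dict[tuple[str, str], dict[tuple[str, int, str], ts.IncubationSeries]]:
    groups: dict = {}
    for s in incubations:
        groups.setdefault((s.station, s.zone), {})[
            (s.treatment, s.replicate, s.population)
        ] = s
    return groups


def _replicates_for(
    arm: dict, treatment: str
) -> list[tuple[int, ts.IncubationSeries, ts.IncubationSeries]]:
    """(replicate, prok_series, virus_series) triples present in full."""
    reps = sorted(
        {r for (t, r, p) in arm if t == treatment and p == "virus"}
    )
    out = []
    for r in reps:
        prok = arm.get((treatment, r, "prokaryote"))
        virus = arm.get((treatment, r, "virus"))
        if prok is not None and virus is not None:
            out.append((r, prok, virus))
    return out


def analyze_sample_approach(
    arm: dict,
    approach: str,
    env: st.EnvSample | None,
    burst_size: float,
) -> dict | None:
    """Rates, FIC, FLC, burst size and turnover for one sample x approach."""
    replicates = _replicates_for(arm, approach)
    if not replicates:
        return None
    insitu_prok = env.prok_abundance if env else None
    insitu_virus = env.viral_abundance if env else None

    per_rep = []
    for rep, prok, virus in replicates:
        p0 = prok.abundances[0]
        if approach == "dilution" and insitu_prok:
            factor = ts.dilution_correction_factor(insitu_prok, p0)
        else:
            factor = 1.0
        rates = ts.rates_for_series(prok, virus, correction_factor=factor)
        fic_val = inf.fic(virus, p0=p0, burst=burst_size, correction=factor)
        seg = ts.detect_extrema(virus)
        per_rep.append(
            {
                "replicate": rep,
                "t0_prokaryotes": p0,
                "t0_viruses": virus.abundances[0],
                "correction_factor": factor,
                "extrema_count": len(seg.points),
                "rates": dataclasses.asdict(rates),
                "fic_percent": fic_val,
            }
        )
        log.debug(
            "%s/%s %s rep %d: %d extrema, VP=%.3g FIC=%.3g",
            prok.station, prok.zone, approach, rep, len(seg.points),
            rates.VP, fic_val,
        )

    summaries = {
        name: _summary_dict(
            ts.summarize_duplicates([r["rates"][name] for r in per_rep])
        )
        for name in ("PG", "mortality", "PG_net", "VP", "VD", "VP_net")
    }
    fic_summary = ts.summarize_duplicates([r["fic_percent"] for r in per_rep])

    # empirical burst size and the FIC rescale it implies (dilution only)
    burst_emp = []
    for r in per_rep:
        try:
            burst_emp.append(
                inf.empirical_burst_size(r["rates"]["VP"], r["rates"]["mortality"])
            )
        except ts.UndefinedResultError:
            burst_emp.append(None)
    defined = [b for b in burst_emp if b is not None]
    burst_summary = (
        _summary_dict(ts.summarize_duplicates(defined)) if defined else None
    )
    rescale = (
        inf.fic_rescale_factor(burst_size, float(np.mean(defined)))
        if approach == "dilution" and defined and np.mean(defined) > 0
        else None
    )

    # turnover from in situ standing stocks, per replicate then averaged
    turnover = {"prokaryotic_d": None, "viral_d": None}
    if insitu_prok and insitu_virus:
        for key, stock, rate_name in (
            ("prokaryotic_d", insitu_prok, "PG"),
            ("viral_d", insitu_virus, "VP"),
        ):
            vals = []
            for r in per_rep:
                try:
                    vals.append(ts.turnover_time(stock, r["rates"][rate_name]))
                except ts.UndefinedResultError:
                    pass
            if vals:
                turnover[key] = _summary_dict(ts.summarize_duplicates(vals))

    # FLC from the mitomycin C arm of the same approach
    flc_out: float | str | None = None
    mitc = _replicates_for(arm, f"{approach}+mitC")
    if mitc:
        fic_mitc = []
        for rep, prok, virus in mitc:
            p0 = prok.abundances[0]
            factor = (
                ts.dilution_correction_factor(insitu_prok, p0)
                if approach == "dilution" and insitu_prok
                else 1.0
            )
            fic_mitc.append(inf.fic(virus, p0=p0, burst=burst_size, correction=factor))
        val = inf.flc(fic_summary, ts.summarize_duplicates(fic_mitc))
        flc_out = "ND" if val is None else val

    return {
        "replicates": per_rep,
        "rate_summaries": summaries,
        "fic": _summary_dict(fic_summary),
        "flc_percent": flc_out,
        "burst_size_assumed": burst_size,
        "burst_size_empirical": burst_summary,
        "fic_rescale_factor": rescale,
        "turnover": turnover,
    }


def run_full_analysis(
    bundle: StudyBundle,
    config: AnalysisConfig | None = None,
    truth: dict | None = None,
) -> dict:
    """Run the whole estimation chain over a study bundle.

    Per sample and approach: piece-wise rates -> duplicate summaries ->
    FIC/FLC/burst/turnover; decay incubations -> ln-linear VD_INT fits;
    then comparative statistics (environmental Spearman matrix, undiluted
    vs dilution rank tests, nutrient/water-mass variation partitioning).
    Missing treatment arms degrade gracefully: their sections are absent.

    When ``truth`` (a :class:`~viroprod.simulate.SimulatedExperiment` truth
    record) is given, a truth-comparison block with relative errors of the
    recovered rates is appended.
    """
    config = config or AnalysisConfig()
    report: dict = {"config": dataclasses.asdict(config), "samples": {}}
    groups = _group_incubations(bundle.incubations)

    for (station, zone), arm in sorted(groups.items()):
        env = bundle.env_for(station, zone)
        sample_out: dict = {}
        for approach in ("undiluted", "dilution"):
            res = analyze_sample_approach(arm, approach, env, config.burst_size)
            if res is not None:
                sample_out[approach] = res
        decay_fits = []
        for rep, virus in sorted(
            (r, s) for (t, r, p), s in arm.items() if t == "decay" and p == "virus"
        ):
            fit = inf.vd_int(virus)
            decay_fits.append({"replicate": rep, **dataclasses.asdict(fit),
                               "detected": fit.detected})
        if decay_fits:
            sample_out["vd_int"] = decay_fits
        if sample_out:
            report["samples"].setdefault(station, {})[zone] = sample_out

    stats_block = _statistics_block(bundle, report["samples"], config)
    if stats_block:
        report["statistics"] = stats_block
    if truth is not None:
        report["truth_comparison"] = _truth_block(report["samples"], truth)
    return report


def _collect_metric(samples: dict, approach: str, metric: str) -> list[float]:
    vals = []
    for zones in samples.values():
        for sample in zones.values():
            block = sample.get(approach)
            if not block:
                continue
            for rep in block["replicates"]:
                vals.append(
                    rep["fic_percent"] if metric == "FIC" else rep["rates"][metric]
                )
    return vals


def _statistics_block(
    bundle: StudyBundle, samples: dict, config: AnalysisConfig
) -> dict:
    out: dict = {}
    env = bundle.env_table
    if len(env) >= 3:
        fields = [
            "depth", "temperature", "salinity", "turbidity",
            "PO4", "NO2", "NO3", "NH4", "O2", "H2S",
            "prok_abundance", "viral_abundance", "vpr",
        ]
        fields = [f for f in fields if f not in config.exclude_env]
        matrix: dict = {}
        for i, fa in enumerate(fields):
            for fb in fields[i + 1:]:
                xa = [getattr(e, fa) for e in env]
                xb = [getattr(e, fb) for e in env]
                if all(v is None for v in xa) or all(v is None for v in xb):
                    continue
                r, p = st.spearman(
                    xa, xb, nd_policy=config.nd_policy, exact=config.exact_spearman
                )
                matrix[f"{fa}~{fb}"] = {"r": r, "p": p, "n": len(env)}
        out["spearman_env"] = matrix

    comparisons: dict = {}
    for metric in ("PG", "mortality", "PG_net", "VP", "VD", "VP_net", "FIC"):
        a = _collect_metric(samples, "undiluted", metric)
        b = _collect_metric(samples, "dilution", metric)
        if a and b:
            res = st.mann_whitney(a, b)
            comparisons[metric] = {
                "U": res.U, "z": res.z, "p": res.p_value,
                "n_undiluted": len(a), "n_dilution": len(b),
            }
    if comparisons:
        out["approach_comparisons"] = comparisons

    if len(env) >= 6:
        vp_block = _variation_partition_block(bundle, samples, config)
        if vp_block:
            out["variation_partitioning"] = vp_block
    return out


def _variation_partition_block(
    bundle: StudyBundle, samples: dict, config: AnalysisConfig
) -> dict:
    out = {}
    for approach in ("undiluted", "dilution"):
        Y, X, Z = [], [], []
        for e in bundle.env_table:
            block = samples.get(e.station, {}).get(e.zone, {}).get(approach)
            if not block:
                continue
            nutrients = st.resolve_below_detection(
                [e.NO2, e.NH4, e.PO4], config.nd_policy
            )
            Y.append([block["fic"]["average"], block["rate_summaries"]["VP"]["average"]])
            X.append(list(nutrients))
            Z.append([e.temperature, e.salinity])
        if len(Y) >= 6:
            part = st.rda_variation_partition(
                np.array(Y), np.array(X), np.array(Z),
                n_perm=config.n_perm, seed=config.seed,
            )
            out[approach] = dataclasses.asdict(part)
    return out


def _truth_block(samples: dict, truth: dict) -> dict:
    """Relative recovery errors of uncorrected rates against the truth record."""
    out: dict = {}
    treatments = truth.get("treatments", {})
    for zones in samples.values():
        for sample in zones.values():
            for approach in ("undiluted", "dilution"):
                block = sample.get(approach)
                t = treatments.get(approach)
                if not block or not t:
                    continue
                entry: dict = {}
                for est_name, true_name in (
                    ("VP", "true_vp"),
                    ("mortality", "true_mortality"),
                ):
                    uncorr = [
                        r["rates"][est_name] / r["correction_factor"]
                        for r in block["replicates"]
                    ]
                    est = float(np.mean(uncorr))
                    tv = t[true_name]
                    entry[est_name] = {
                        "estimate_uncorrected": est,
                        "truth": tv,
                        "relative_error": (est - tv) / tv if tv else None,
                    }
                fic_truth = 100.0 * t["total_lysed"] / t["t0_prokaryotes"]
                entry["FIC_truth_percent_at_true_burst"] = fic_truth
                out[approach] = entry
    return out


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json (deterministic, sorted keys) plus flat CSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=_jsonify))
    rows = []
    for station, zones in report.get("samples", {}).items():
        for zone, sample in zones.items():
            for approach in ("undiluted", "dilution"):
                block = sample.get(approach)
                if not block:
                    continue
                for rep in block["replicates"]:
                    rows.append(
                        {
                            "station": station, "zone": zone,
                            "approach": approach, "replicate": rep["replicate"],
                            **rep["rates"], "fic_percent": rep["fic_percent"],
                        }
                    )
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "rates.csv", index=False)
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
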