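"""End-to-end orchestration: simulate → render → analyze → fit → report.

The experiment drivers in this module reproduce the assay designs of an
in vitro reconstitution study of microtubule dynamics:

* a concentration series of growth velocities, fit for k_a / k_d / C_c;
* templated-nucleation lag assays, fit to the constrained Hill law;
* spontaneous-nucleation field counts, fit for the critical concentration;
* catastrophe counting per channel;
* long-interval imaging of depolymerizing stabilized seeds.

:func:`run_pipeline` runs every experiment in a :class:`RunConfig` with
per-condition failure isolation, and writes delimited-text result tables
plus a human-readable report.  All randomness derives deterministically
from the run seed, so identical configs and seeds give identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics_model import (
    ExperimentCondition,
    KineticParams,
    load_default_params,
    write_condition_table,
)
from .estimators import (
    CatastropheFrequency,
    HillFit,
    LinearRateFit,
    SpontaneousFit,
    catastrophe_frequency,
    fit_growth_kinetics,
    fit_nucleation_hill,
    fit_spontaneous_nucleation,
)
from .kymograph_render import OpticsConfig, render_kymograph
from .synthetic_data import (
    GROWTH,
    NucleationRecord,
    sample_gmpcpp_depolymerization,
    sample_nucleation_lags,
    sample_spontaneous_count,
    sample_trajectory,
)
from .trace_analysis import (
    DynamicsSummary,
    PhaseSegment,
    depolymerization_rate,
    segment_phases,
    summarize_dynamics,
    track_tip,
    trajectory_to_segments,
)

log = logging.getLogger("mtdynamics")

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "derive_seed",
    "measure_growth_kinetics",
    "measure_nucleation",
    "measure_spontaneous",
    "measure_catastrophe",
    "measure_depolymerization",
    "run_pipeline",
    "report",
    "write_segment_table",
    "read_segment_table",
    "write_nucleation_table",
    "read_nucleation_table",
]


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed (< 2³¹) from a master seed and string tags."""
    h = hashlib.sha256(repr((int(master),) + tuple(map(str, tags))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# experiment drivers


def measure_growth_kinetics(
    params: KineticParams,
    tubulin_uM: list[float],
    n_events: int,
    seed: int,
    label: str = "condition",
    duration_min: float = 10.0,
    render: bool = True,
    optics: OpticsConfig | None = None,
    noise_cv: float = 0.10,
    min_segment: int = 5,
    min_growth_duration_s: float = 60.0,
    min_peak_fraction: float = 0.9,
) -> tuple[LinearRateFit, dict[float, list[float]]]:
    """Concentration series of growth velocities → kinetic regression.

    Simulates ``n_events`` filaments per tubulin concentration; with
    ``render=True`` each trajectory is imaged as a kymograph, the tip is
    tracked and phases are segmented, and growth-segment slopes are the
    velocity samples (the full imaging loop).  With ``render=False`` the
    generator's own growth slopes are used (fast path).  Only growth
    segments lasting at least ``min_growth_duration_s`` enter the fit, and
    tracking uses a strict resolution floor (``min_peak_fraction`` of the
    resolved amplitude) so slopes are fit on fully resolved tip positions
    only — the automated analogue of measuring slopes on clearly resolved
    kymograph excursions.
    """
    optics = optics or OpticsConfig()
    samples: dict[float, list[float]] = {}
    for c in tubulin_uM:
        cond = ExperimentCondition(c, label=label)
        vels: list[float] = []
        for k in range(n_events):
            traj = sample_trajectory(
                cond, params, duration_min * 60.0,
                derive_seed(seed, "kin", label, c, k), noise_cv=noise_cv,
            )
            if render:
                kymo = render_kymograph(
                    traj, optics, derive_seed(seed, "kin-img", label, c, k)
                )
                trace = track_tip(kymo, min_peak_fraction=min_peak_fraction)
                if trace.n_present < 2 * min_segment:
                    continue
                segs = segment_phases(trace, min_segment=min_segment)
            else:
                segs = trajectory_to_segments(traj)
            vels.extend(
                s.slope_um_min
                for s in segs
                if s.phase == GROWTH
                and s.t_end_s - s.t_start_s >= min_growth_duration_s
            )
        samples[c] = vels
    return fit_growth_kinetics(samples), samples


def measure_nucleation(
    params: KineticParams,
    tubulin_uM: list[float],
    n_seeds: int,
    seed: int,
    label: str = "condition",
    t_max_s: float = 300.0,
    window_s: float = 60.0,
) -> tuple[HillFit, dict[float, list[NucleationRecord]]]:
    """Templated nucleation lags → fraction within 1 min → Hill fit."""
    records: dict[float, list[NucleationRecord]] = {}
    fractions = []
    for c in tubulin_uM:
        cond = ExperimentCondition(c, label=label)
        recs = sample_nucleation_lags(
            cond, params, n_seeds, t_max_s, derive_seed(seed, "nuc", label, c)
        )
        records[c] = recs
        fractions.append(
            np.mean([(not r.censored) and r.lag_s <= window_s for r in recs])
        )
    fit = fit_nucleation_hill(tubulin_uM, fractions)
    return fit, records


def measure_spontaneous(
    params: KineticParams,
    tubulin_uM: list[float],
    n_fields: int,
    seed: int,
    label: str = "condition",
) -> tuple[SpontaneousFit, dict[float, list[int]]]:
    """Per-field spontaneous nucleation counts → linear critical-conc fit."""
    counts: dict[float, list[int]] = {}
    for c in tubulin_uM:
        cond = ExperimentCondition(c, label=label, seeded=False)
        counts[c] = [
            sample_spontaneous_count(
                cond, params, derive_seed(seed, "spont", label, c, k)
            )
            for k in range(n_fields)
        ]
    return fit_spontaneous_nucleation(counts), counts


def measure_catastrophe(
    params: KineticParams,
    tubulin_uM: float,
    n_filaments: int,
    seed: int,
    label: str = "condition",
    duration_min: float = 10.0,
    render: bool = False,
    optics: OpticsConfig | None = None,
    n_boot: int = 10_000,
) -> tuple[CatastropheFrequency, DynamicsSummary]:
    """Catastrophe events over total growth time in one channel."""
    cond = ExperimentCondition(tubulin_uM, label=label)
    seg_lists: list[list[PhaseSegment]] = []
    for k in range(n_filaments):
        traj = sample_trajectory(
            cond, params, duration_min * 60.0, derive_seed(seed, "cat", label, k)
        )
        if render:
            kymo = render_kymograph(
                traj, optics or OpticsConfig(), derive_seed(seed, "cat-img", label, k)
            )
            segs = segment_phases(track_tip(kymo))
        else:
            segs = trajectory_to_segments(traj)
        seg_lists.append(segs)
    summary = summarize_dynamics(seg_lists, cond)
    freq = catastrophe_frequency(summary, n_boot, derive_seed(seed, "cat-boot", label))
    return freq, summary


def measure_depolymerization(
    params: KineticParams,
    seed: int,
    label: str = "condition",
    duration_min: float = 600.0,
    frame_interval_min: float = 1.0,
    initial_length_um: float = 8.0,
    optics: OpticsConfig | None = None,
) -> float:
    """Render a shrinking stabilized seed, track it, fit the shrink rate.

    Returns the shrinkage speed in µm/min (0-clamped rates are returned
    as fitted, which may be slightly negative for a static seed).
    """
    traj = sample_gmpcpp_depolymerization(
        params,
        duration_min,
        frame_interval_min,
        derive_seed(seed, "depoly", label),
        initial_length_um=initial_length_um,
    )
    optics = optics or OpticsConfig(frame_interval_s=frame_interval_min * 60.0)
    kymo = render_kymograph(
        traj, optics, derive_seed(seed, "depoly-img", label), seed_length_um=0.0
    )
    trace = track_tip(kymo)
    return depolymerization_rate(trace)


# ---------------------------------------------------------------------------
# event tables (delimited text)

_SEGMENT_COLS = ["filament_id", "condition", "t_start_s", "t_end_s", "slope_um_min", "phase"]
_NUCLEATION_COLS = ["seed_id", "lag_s", "censored"]


def write_segment_table(
    path: str | Path, segments_per_filament: list[list[PhaseSegment]], condition: str
) -> None:
    rows = [
        {
            "filament_id": fid,
            "condition": condition,
            "t_start_s": s.t_start_s,
            "t_end_s": s.t_end_s,
            "slope_um_min": s.slope_um_min,
            "phase": s.phase,
        }
        for fid, segs in enumerate(segments_per_filament)
        for s in segs
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLS).to_csv(path, index=False)


def read_segment_table(path: str | Path) -> dict[str, list[list[PhaseSegment]]]:
    """Read segments grouped by condition then filament.

    Unknown columns are tolerated; a malformed row raises with its line
    number (header is line 1).
    """
    df = pd.read_csv(path)
    for col in _SEGMENT_COLS:
        if col not in df.columns:
            raise ValueError(f"segment table missing mandatory column {col!r}")
    out: dict[str, dict[int, list[PhaseSegment]]] = {}
    for idx, row in df.iterrows():
        try:
            seg = PhaseSegment(
                float(row["t_start_s"]),
                float(row["t_end_s"]),
                float(row["slope_um_min"]),
                str(row["phase"]),
            )
            fid = int(row["filament_id"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row at line {idx + 2} of {path}: {exc}") from exc
        out.setdefault(str(row["condition"]), {}).setdefault(fid, []).append(seg)
    return {
        cond: [segs for _, segs in sorted(byfil.items())]
        for cond, byfil in out.items()
    }


def write_nucleation_table(path: str | Path, records: list[NucleationRecord]) -> None:
    rows = [
        {"seed_id": r.seed_id, "lag_s": r.lag_s, "censored": r.censored}
        for r in records
    ]
    pd.DataFrame(rows, columns=_NUCLEATION_COLS).to_csv(path, index=False)


def read_nucleation_table(path: str | Path) -> list[NucleationRecord]:
    df = pd.read_csv(path)
    for col in _NUCLEATION_COLS:
        if col not in df.columns:
            raise ValueError(f"nucleation table missing mandatory column {col!r}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                NucleationRecord(int(row["seed_id"]), float(row["lag_s"]), bool(row["censored"]))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row at line {idx + 2} of {path}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# run configuration and results


@dataclass
class RunConfig:
    """Full description of a reproducible pipeline run."""

    seed: int
    outdir: Path = Path("mtdyn_results")
    conditions: dict[str, KineticParams] = field(default_factory=load_default_params)
    growth_kinetics: list[dict] = field(default_factory=list)
    nucleation: list[dict] = field(default_factory=list)
    spontaneous: list[dict] = field(default_factory=list)
    catastrophe: list[dict] = field(default_factory=list)
    depolymerization: list[dict] = field(default_factory=list)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    render: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ValueError("config must be a mapping with a mandatory 'seed'")
        conditions = load_default_params()
        for label, kw in (raw.get("conditions") or {}).items():
            conditions[label] = KineticParams(**kw)
        optics = OpticsConfig(**(raw.get("optics") or {}))
        return cls(
            seed=int(raw["seed"]),
            outdir=Path(raw.get("outdir", "mtdyn_results")),
            conditions=conditions,
            growth_kinetics=raw.get("growth_kinetics") or [],
            nucleation=raw.get("nucleation") or [],
            spontaneous=raw.get("spontaneous") or [],
            catastrophe=raw.get("catastrophe") or [],
            depolymerization=raw.get("depolymerization") or [],
            optics=optics,
            render=bool(raw.get("render", True)),
        )

    @classmethod
    def paper_defaults(cls, seed: int = 1, outdir: str | Path = "mtdyn_results") -> "RunConfig":
        """The bundled default study design (control + 500 nM CKAP2)."""
        return cls(
            seed=seed,
            outdir=Path(outdir),
            growth_kinetics=[
                {"condition": "control", "tubulin_uM": [5, 10, 14], "n_events": 60},
                {
                    "condition": "ckap2_500nM",
                    "tubulin_uM": [0.05, 0.1, 0.2, 0.3],
                    "n_events": 60,
                },
            ],
            nucleation=[
                {
                    "condition": "control",
                    "tubulin_uM": [2, 4, 6, 8, 10, 12, 16, 20],
                    "n_seeds": 150,
                },
                {
                    "condition": "ckap2_500nM",
                    "tubulin_uM": [0.01, 0.02, 0.035, 0.05, 0.075, 0.1, 0.15, 0.2],
                    "n_seeds": 150,
                },
            ],
            spontaneous=[
                {"condition": "control", "tubulin_uM": [26, 30, 35, 40, 45, 50], "n_fields": 20},
                {
                    "condition": "ckap2_200nM",
                    "tubulin_uM": [0.3, 0.35, 0.4, 0.45, 0.5],
                    "n_fields": 14,
                },
            ],
            catastrophe=[
                {"condition": "control", "tubulin_uM": 8.0, "n_filaments": 40},
            ],
            depolymerization=[{"condition": "control", "duration_min": 600}],
        )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "conditions": {k: asdict(v) for k, v in sorted(self.conditions.items())},
            "growth_kinetics": self.growth_kinetics,
            "nucleation": self.nucleation,
            "spontaneous": self.spontaneous,
            "catastrophe": self.catastrophe,
            "depolymerization": self.depolymerization,
            "optics": asdict(self.optics),
            "render": self.render,
        }
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Everything a pipeline run produced, traceable to its config hash."""

    kinetic_fits: dict[str, LinearRateFit] = field(default_factory=dict)
    hill_fits: dict[str, HillFit] = field(default_factory=dict)
    spontaneous_fits: dict[str, SpontaneousFit] = field(default_factory=dict)
    catastrophe: dict[str, CatastropheFrequency] = field(default_factory=dict)
    summaries: dict[str, DynamicsSummary] = field(default_factory=dict)
    depoly_rates: dict[str, float] = field(default_factory=dict)
    nucleation_records: dict[str, dict[float, list[NucleationRecord]]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> ResultsBundle:
    """Run every experiment in ``config``; failures are isolated per item.

    A failing experiment is logged and recorded in ``bundle.errors``; the
    remaining experiments still run.  With ``write_outputs`` the result
    tables, the condition table and a report are written under
    ``config.outdir``.
    """
    bundle = ResultsBundle(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _version(),
        }
    )

    def guarded(kind: str, spec: dict, fn):
        label = spec.get("condition", "?")
        try:
            if label not in config.conditions:
                raise KeyError(f"condition {label!r} has no parameters")
            fn(label, config.conditions[label])
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            msg = f"{kind}[{label}]: {exc}"
            log.error(msg)
            bundle.errors.append(msg)

    for spec in config.growth_kinetics:
        def _kin(label, params, spec=spec):
            fit, _ = measure_growth_kinetics(
                params,
                list(spec["tubulin_uM"]),
                int(spec.get("n_events", 60)),
                config.seed,
                label=label,
                duration_min=float(spec.get("duration_min", 10.0)),
                render=bool(spec.get("render", config.render)),
                optics=config.optics,
            )
            bundle.kinetic_fits[label] = fit
        guarded("growth_kinetics", spec, _kin)

    for spec in config.nucleation:
        def _nuc(label, params, spec=spec):
            fit, recs = measure_nucleation(
                params,
                list(spec["tubulin_uM"]),
                int(spec.get("n_seeds", 150)),
                config.seed,
                label=label,
            )
            bundle.hill_fits[label] = fit
            bundle.nucleation_records[label] = recs
        guarded("nucleation", spec, _nuc)

    for spec in config.spontaneous:
        def _spont(label, params, spec=spec):
            fit, _ = measure_spontaneous(
                params,
                list(spec["tubulin_uM"]),
                int(spec.get("n_fields", 20)),
                config.seed,
                label=label,
            )
            bundle.spontaneous_fits[label] = fit
        guarded("spontaneous", spec, _spont)

    for spec in config.catastrophe:
        def _cat(label, params, spec=spec):
            freq, summary = measure_catastrophe(
                params,
                float(spec["tubulin_uM"]),
                int(spec.get("n_filaments", 40)),
                config.seed,
                label=label,
                duration_min=float(spec.get("duration_min", 10.0)),
                render=bool(spec.get("render", False)),
                optics=config.optics,
            )
            bundle.catastrophe[label] = freq
            bundle.summaries[label] = summary
        guarded("catastrophe", spec, _cat)

    for spec in config.depolymerization:
        def _dep(label, params, spec=spec):
            rate = measure_depolymerization(
                params,
                config.seed,
                label=label,
                duration_min=float(spec.get("duration_min", 600.0)),
            )
            bundle.depoly_rates[label] = rate
        guarded("depolymerization", spec, _dep)

    if write_outputs:
        _write_bundle(config, bundle)
    return bundle


def _version() -> str:
    try:
        return metadata.version("mtdynamics")
    except metadata.PackageNotFoundError:
        return "unknown"


def _fmt(value: float, se: float, unit: str = "") -> str:
    return f"{value:.4g} ± {se:.2g}{(' ' + unit) if unit else ''}"


def report(bundle: ResultsBundle, outdir: str | Path | None = None) -> str:
    """Human-readable fit summary; optionally writes figures to ``outdir``."""
    lines = [
        "mtdynamics results",
        f"config {bundle.provenance.get('config_hash', '?')}  "
        f"seed {bundle.provenance.get('seed', '?')}  "
        f"version {bundle.provenance.get('version', '?')}",
        "",
    ]
    for label, fit in bundle.kinetic_fits.items():
        lines += [
            f"[{label}] growth kinetics (n = {fit.n_points} concentrations, R² = {fit.r_squared:.4f})",
            f"  k_a = {_fmt(fit.k_a, fit.k_a_se, 'dimers µM⁻¹ s⁻¹')}",
            f"  k_d = {_fmt(fit.k_d, fit.k_d_se, 'dimers s⁻¹')}",
            f"  C_c = {_fmt(fit.C_c, fit.C_c_se, 'µM')}",
        ]
    for label, fit in bundle.hill_fits.items():
        lines += [
            f"[{label}] templated nucleation (Hill, endpoints 0→1)",
            f"  C = {_fmt(fit.C, fit.C_se, 'µM')}",
            f"  s = {_fmt(fit.s, fit.s_se)}",
        ]
    for label, fit in bundle.spontaneous_fits.items():
        lines += [
            f"[{label}] spontaneous nucleation",
            f"  slope = {_fmt(fit.slope, fit.slope_se, 'MT field⁻¹ µM⁻¹')}",
            f"  C_c = {_fmt(fit.critical_conc, fit.critical_conc_se, 'µM')}",
        ]
    for label, f in bundle.catastrophe.items():
        lines.append(
            f"[{label}] catastrophe frequency = {f.frequency:.3g} min⁻¹ "
            f"(CI {f.ci_low:.3g}–{f.ci_high:.3g}; {f.n_events} events / "
            f"{f.total_time_min:.1f} min growth)"
        )
    for label, rate in bundle.depoly_rates.items():
        lines.append(f"[{label}] GMPCPP seed shrinkage = {rate:.4g} µm/min")
    if bundle.errors:
        lines += ["", "errors:"] + [f"  {e}" for e in bundle.errors]
    text = "\n".join(lines) + "\n"

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.txt").write_text(text)
        _write_figures(bundle, outdir)
    return text


def _write_figures(bundle: ResultsBundle, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if bundle.kinetic_fits:
        fig, ax = plt.subplots(figsize=(4, 3))
        labels = list(bundle.kinetic_fits)
        ka = [bundle.kinetic_fits[m].k_a for m in labels]
        se = [bundle.kinetic_fits[m].k_a_se for m in labels]
        ax.bar(labels, ka, yerr=se, color="#4878a8")
        ax.set_ylabel("k_a (dimers µM⁻¹ s⁻¹)")
        ax.set_yscale("log")
        fig.tight_layout()
        fig.savefig(outdir / "ka_by_condition.png", dpi=150)
        plt.close(fig)
    if bundle.hill_fits:
        fig, ax = plt.subplots(figsize=(4, 3))
        from .dynamics_model import hill_probability

        for label, fit in bundle.hill_fits.items():
            c = np.geomspace(fit.C / 20, fit.C * 20, 200)
            ax.semilogx(c, hill_probability(c, fit.C, fit.s), label=label)
        ax.set_xlabel("tubulin (µM)")
        ax.set_ylabel("P(nucleate ≤ 1 min)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "nucleation_hill.png", dpi=150)
        plt.close(fig)


def _write_bundle(config: RunConfig, bundle: ResultsBundle) -> None:
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    write_condition_table(outdir / "conditions.csv", config.conditions)

    def df_to_csv(rows: list[dict], name: str) -> None:
        if rows:
            pd.DataFrame(rows).to_csv(outdir / name, index=False)

    df_to_csv(
        [
            {"condition": m, **asdict(f)}
            for m, f in bundle.kinetic_fits.items()
        ],
        "kinetic_fits.csv",
    )
    df_to_csv(
        [{"condition": m, **asdict(f)} for m, f in bundle.hill_fits.items()],
        "hill_fits.csv",
    )
    df_to_csv(
        [{"condition": m, **asdict(f)} for m, f in bundle.spontaneous_fits.items()],
        "spontaneous_fits.csv",
    )
    df_to_csv(
        [{"condition": m, **asdict(f)} for m, f in bundle.catastrophe.items()],
        "catastrophe.csv",
    )
    df_to_csv(
        [
            {"condition": m, "v_depoly_um_min": r}
            for m, r in bundle.depoly_rates.items()
        ],
        "depolymerization.csv",
    )
    for label, recs_by_conc in bundle.nucleation_records.items():
        for c, recs in recs_by_conc.items():
            write_nucleation_table(
                outdir / f"nucleation_{label}_{c:g}uM.csv", recs
            )
    report(bundle, outdir)
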