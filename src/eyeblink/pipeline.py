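"""End-to-end pipeline: simulate/ingest -> preprocess -> decompose ->
response metrics -> group statistics -> report.

Artifacts are delimited text tables with a small comment header carrying a
schema version and a hash of the run configuration, so every output is
traceable to the exact settings that produced it.  Each stage logs trial
counts in/out (and why trials were excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as dec
from . import response_metrics as rm
from . import stats as st
from .preprocess import normalize_session
from .protocol import Phase, ProtocolConfig, TrialKind
from .simulate import CohortSpec, GroupSpec, SimulationConfig, ground_truth_table, iter_cohort_sessions

log = logging.getLogger("eyeblink")

SCHEMA_VERSION = 1

SESSION_COLUMNS = [
    "subject_id", "group", "age_days", "phase", "session",
    "n_trials", "probability", "amplitude", "percent_cr",
]


@dataclass
class RunConfig:
    """Run settings: cohort composition, protocol, analysis parameters.

    Serializes losslessly to/from a YAML mapping; every field has the
    protocol's default.
    """

    seed: int = 0
    groups: list = field(default_factory=lambda: [
        {"label": "wt", "n_subjects": 8},
        {"label": "mut", "n_subjects": 8, "overrides": {"p_max": 0.35}},
    ])
    protocol: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    bin_width: float = dec.DEFAULT_BIN_WIDTH
    cr_threshold: float = 0.15
    smooth_width_ms: float = 10.0
    ur_first_session_only: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise st.DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            groups=tuple(
                GroupSpec(g["label"], g["n_subjects"], g.get("overrides", {}))
                for g in self.groups
            ),
            protocol=ProtocolConfig(**self.protocol),
            base_config=SimulationConfig(**self.simulation),
            master_seed=self.seed,
        )


def config_hash(cfg: RunConfig | dict) -> str:
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else cfg
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Table IO


def write_table(df: pd.DataFrame, path: Path | str, cfg_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        if cfg_hash:
            fh.write(f"# config_sha256: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path | str, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise st.DataError(
                f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
            )
    return df


# ---------------------------------------------------------------------------
# Session-level analysis


def analyze_session(
    traces: list,
    bin_width: float = dec.DEFAULT_BIN_WIDTH,
    cr_threshold: float = 0.15,
    smooth_width_ms: float = 10.0,
    with_ur: bool = False,
) -> tuple[dict, list[dict], dict]:
    """Analyze one session of raw traces.

    Returns (session metrics row, per-trial metric rows for probe/US trials,
    exclusion counts).
    """
    trials = normalize_session(traces)
    excl = {"n_raw": len(trials)}
    invalid = [t for t in trials if not t.valid]
    excl["invalid"] = len(invalid)
    for t in invalid:
        excl[t.exclusion_reason.value] = excl.get(t.exclusion_reason.value, 0) + 1

    metrics = dec.session_metrics(
        trials, bin_width=bin_width, cr_threshold=cr_threshold
    )

    trial_rows: list[dict] = []
    session_has_crs = False
    for t in trials:
        if not t.valid:
            continue
        if t.plan.kind is TrialKind.CS_ONLY:
            cm = rm.cr_timing(t, smooth_width_ms=smooth_width_ms)
            opening = rm.detect_photic_opening(t, session_has_crs)
            if cm.is_cr:
                session_has_crs = True
            trial_rows.append(
                dict(
                    block=t.plan.block_index, trial=t.plan.trial_index,
                    kind=t.plan.kind.value,
                    cs_onset_ms=t.markers.get("cs_onset"),
                    us_onset_ms=t.markers.get("us_onset"),
                    status="cr" if cm.is_cr else ("excluded" if cm.excluded else "none"),
                    onset_latency_ms=cm.onset_latency_ms,
                    rise_time_10_90_ms=cm.rise_time_10_90_ms,
                    peak_latency_ms=cm.peak_latency_ms,
                    peak_amplitude=cm.peak_amplitude,
                    opening_detected=opening.detected,
                    opening_depth=opening.depth,
                )
            )
        elif with_ur and t.markers.get("us_onset") is not None:
            try:
                um = rm.ur_metrics(t, smooth_width_ms=smooth_width_ms)
            except rm.UndetectedURError:
                continue
            trial_rows.append(
                dict(
                    block=t.plan.block_index, trial=t.plan.trial_index,
                    kind=t.plan.kind.value,
                    cs_onset_ms=t.markers.get("cs_onset"),
                    us_onset_ms=t.markers.get("us_onset"),
                    status="ur",
                    ur_latency_ms=um.latency_ms, ur_rise_time_ms=um.rise_time_ms,
                    ur_peak_velocity=um.peak_velocity,
                )
            )
    return metrics, trial_rows, excl


def analyze_cohort(
    spec: CohortSpec, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze a full cohort; returns (per-session metrics
    table, per-trial metrics table)."""
    cfg = cfg or RunConfig()
    session_rows, trial_rows = [], []
    for rec, phase, s, traces in iter_cohort_sessions(spec):
        with_ur = not cfg.ur_first_session_only or (
            phase is Phase.ACQUISITION and s == 0
        )
        metrics, trows, excl = analyze_session(
            traces, cfg.bin_width, cfg.cr_threshold, cfg.smooth_width_ms, with_ur
        )
        log.info(
            "%s %s s%d: %d trials in, %d invalid (%s)",
            rec.subject_id, phase.value, s, excl["n_raw"], excl["invalid"],
            {k: v for k, v in excl.items() if k not in ("n_raw", "invalid")},
        )
        base = dict(
            subject_id=rec.subject_id, group=rec.group, age_days=rec.age_days,
            phase=phase.value, session=s,
        )
        session_rows.append({**base, **metrics})
        for r in trows:
            trial_rows.append({**base, **r})
    return pd.DataFrame(session_rows), pd.DataFrame(trial_rows)


# ---------------------------------------------------------------------------
# Group statistics and report


def compare_groups(
    session_metrics: pd.DataFrame, metrics: tuple[str, ...] = ("probability", "amplitude", "percent_cr")
) -> dict:
    """The standard two-group battery on acquisition data: last-four-session
    unpaired t-test (with Cohen's d') and mixed-design RM ANOVA per metric,
    plus the extinction/savings paired contrasts when those phases exist."""
    curves = st.build_learning_curves(session_metrics)
    acq = curves[curves["phase"] == "acquisition"]
    groups = sorted(acq["group"].unique())
    results: dict = {"groups": groups, "metrics": {}}
    for m in metrics:
        if m not in acq.columns or acq[m].isna().all():
            continue
        entry: dict = {}
        if len(groups) >= 2:
            try:
                last4 = st.last_four_mean(acq, "acquisition", metrics=(m,))
                if len(groups) == 2:
                    a = last4[last4["group"] == groups[0]][m].to_numpy()
                    b = last4[last4["group"] == groups[1]][m].to_numpy()
                    entry["last_four_t"] = st.unpaired_t(a, b)
                else:
                    entry["last_four_anova"] = st.oneway_anova_bonferroni(
                        {g: last4[last4["group"] == g][m].to_numpy() for g in groups},
                        planned_pairs=[(groups[0], g) for g in groups[1:]],
                    )
                if "age_days" in last4.columns:
                    entry["ancova_age"] = st.ancova_age_tukey(
                        last4.rename(columns={m: "value"}), dv="value"
                    )
            except st.UsageError as err:
                log.warning("skipping last-four tests for %s: %s", m, err)
            try:
                sub = acq.rename(columns={m: "value"}).dropna(subset=["value"])
                entry["rm_anova"] = st.rm_anova_2way(sub)
            except st.UsageError as err:
                log.warning("skipping RM ANOVA for %s: %s", m, err)
        results["metrics"][m] = entry
    if {"extinction", "reacquisition"} <= set(curves["phase"].unique()):
        results["savings"] = st.savings_summary(curves)
    return results


def format_report(results: dict) -> str:
    """Human-readable text block of the statistical battery."""
    lines = [f"Groups: {', '.join(results['groups'])}", ""]
    for m, entry in results["metrics"].items():
        lines.append(f"== {m} ==")
        if "last_four_t" in entry:
            lines.append(f"  last four sessions, unpaired t: {entry['last_four_t'].report()}")
        if "last_four_anova" in entry:
            r = entry["last_four_anova"]
            lines.append(f"  last four sessions, one-way ANOVA: {r.report()}")
            for pair, d in r.extra["pairwise"].items():
                lines.append(
                    f"    {pair[0]} vs {pair[1]}: p_adj = {d['p_adj']:.3g}"
                    + (f", d' = {d['dprime']:.3g}" if d["dprime"] is not None else "")
                )
        if "ancova_age" in entry:
            lines.append(f"  ANCOVA (age covariate): {entry['ancova_age'].report()}")
        if "rm_anova" in entry:
            for eff, r in entry["rm_anova"].items():
                lines.append(f"  RM ANOVA {eff}: {r.report()}")
        lines.append("")
    for g, d in results.get("savings", {}).items():
        lines.append(f"== savings, group {g} ==")
        for contrast, r in d.items():
            lines.append(f"  {contrast}: {r.report() if hasattr(r, 'report') else r}")
        lines.append("")
    return "\n".join(lines)


def render_report(
    session_metrics: pd.DataFrame, results: dict, outdir: Path | str
) -> list[Path]:
    """Write learning-curve figures (group mean ± SEM per session) and the
    text report; returns the artifact paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    acq = session_metrics[session_metrics["phase"] == "acquisition"]
    fig, axes = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for metric, ax in zip(("probability", "amplitude"), axes):
        for g, sub in acq.groupby("group"):
            agg = sub.groupby("session")[metric].agg(["mean", "sem"])
            ax.errorbar(agg.index + 1, agg["mean"], yerr=agg["sem"], label=str(g), capsize=2)
        ax.set_ylabel(f"response {metric}")
        ax.legend(frameon=False)
    axes[-1].set_xlabel("acquisition session")
    fig.tight_layout()
    p = outdir / "learning_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    rpt = outdir / "stats_report.txt"
    rpt.write_text(format_report(results) if results.get("metrics") else "no comparisons\n")
    paths.append(rpt)
    return paths


def plot_decomposition(values: np.ndarray, outpath: Path | str, bin_width: float = dec.DEFAULT_BIN_WIDTH) -> Path:
    """Histogram + reflected-failure/response-mass figure for one session."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = dec.build_histogram(np.asarray(values, float), bin_width)
    res = dec.reflect_and_decompose(hist)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(5, 5), sharex=True)
    ax1.bar(hist.centers, hist.counts, width=bin_width * 0.9, color="0.6")
    ax1.bar(res.bin_centers, res.nonresponse_mass, width=bin_width * 0.9, color="0.8")
    ax1.set_ylabel("trials (non-response shaded)")
    ax2.bar(res.bin_centers, res.response_mass, width=bin_width * 0.9, color="k")
    ax2.axvline(0.15, color="r", lw=1)
    ax2.set_xlabel("normalized peak amplitude")
    ax2.set_ylabel("response mass")
    ax1.set_title(
        f"p = {res.probability:.2f}"
        + (f", amplitude = {res.amplitude:.2f}" if res.amplitude is not None else "")
    )
    fig.tight_layout()
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath


def run_pipeline(cfg: RunConfig, outdir: Path | str) -> dict[str, Path]:
    """Full deterministic run: simulate -> analyze -> stats -> report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(outdir)
    chash = config_hash(cfg)
    spec = cfg.cohort_spec()
    sess, trials = analyze_cohort(spec, cfg)
    gt = ground_truth_table(spec)
    write_table(sess, outdir / "session_metrics.csv", chash)
    write_table(trials, outdir / "trial_metrics.csv", chash)
    write_table(gt, outdir / "ground_truth.csv", chash)
    results = compare_groups(sess) if sess["group"].nunique() >= 2 else {"groups": [], "metrics": {}}
    artifacts = render_report(sess, results, outdir)
    return {
        "session_metrics": outdir / "session_metrics.csv",
        "trial_metrics": outdir / "trial_metrics.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "report": artifacts[-1],
        "figures": artifacts[0],
    }
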