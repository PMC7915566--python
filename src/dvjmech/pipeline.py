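"""Study orchestration: generate -> analyze -> statistics -> report.

One study run emulates the emulated experiment's design: a cohort of
subjects is captured in two sessions (pre-exercise baseline and 48 h after
eccentric exercise), three drop-vertical-jump trials per session are
analyzed through the full pipeline and averaged, and every outcome variable
is compared pre vs post with a paired t-test and a percent change of the
group means.  A companion summary covers the muscle-damage indicator panel
(isometric torque, soreness, creatine kinase) with its reliability layer.

Every run is deterministic given the config seed, and the emitted report
carries the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import synthetic as syn
from .metrics import DVJMetrics, METRIC_UNITS, analyze_trial, average_trials
from .model import build_body_model
from .stats import (paired_t, percent_change, rm_anova_oneway,
                    test_retest_reliability)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of one study run; defaults follow the emulated protocol."""

    n_subjects: int = 13
    trials_per_subject: int = 3
    preset_pre: str = "baseline"
    preset_post: str = "damaged48h"
    seed: int = 0
    session_rho: float = syn.SESSION_RHO
    marker_noise_sd: float = syn.MARKER_NOISE_SD_M
    force_noise_sd: float = syn.FORCE_NOISE_SD_N
    threshold: float = 10.0
    cutoff: float = 15.0
    filter_order: int = 4
    anthropometric_table: str = "deLeva1996"
    stiffness_mode: str = "instants"
    alpha: float = 0.05
    side: str = "R"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.trials_per_subject < 1:
            raise ConfigError("trials_per_subject must be >= 1")
        for name in (self.preset_pre, self.preset_post):
            if name not in syn.PRESET_MEANS:
                raise ConfigError(
                    f"unknown preset {name!r}; valid: "
                    f"{sorted(syn.PRESET_MEANS)}")
        if self.anthropometric_table not in ("deLeva1996", "dempster1955"):
            raise ConfigError(
                f"unknown anthropometric table "
                f"{self.anthropometric_table!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    config: RunConfig
    trials: pd.DataFrame        # one row per subject x session x trial
    subject_means: pd.DataFrame  # one row per subject x session
    summary: pd.DataFrame       # one row per outcome variable
    n_skipped_trials: int = 0
    text: str = ""


def _trial_seed(base: int, subject: int, session: int, trial: int) -> int:
    return (base * 100003 + subject * 1013 + session * 101 + trial) % (2**31)


def run_study(config: RunConfig) -> StudyReport:
    """Execute one full synthetic pre/post study."""
    rng = np.random.default_rng(config.seed)
    sessions = {0: config.preset_pre, 1: config.preset_post}
    trial_rows = []
    mean_rows = []
    skipped = 0
    for si in range(config.n_subjects):
        subject = syn.sample_subject(rng)
        model = build_body_model(subject, config.anthropometric_table)
        static = syn.generate_static_trial(
            subject, marker_noise_sd=config.marker_noise_sd,
            force_noise_sd=config.force_noise_sd,
            seed=_trial_seed(config.seed, si, 9, 0), model=model)
        conditions = syn.sample_feasible_paired_conditions(
            rng, subject, model, pre=config.preset_pre,
            post=config.preset_post, rho=config.session_rho)
        for sess, params in enumerate(conditions):
            per_trial = []
            for k in range(config.trials_per_subject):
                from dataclasses import replace
                p = replace(params,
                            marker_noise_sd=config.marker_noise_sd,
                            force_noise_sd=config.force_noise_sd,
                            seed=_trial_seed(config.seed, si, sess, k))
                try:
                    trial = syn.generate_dvj_trial(subject, p, model)
                    res = analyze_trial(
                        trial, static, side=config.side,
                        threshold=config.threshold, cutoff=config.cutoff,
                        order=config.filter_order,
                        anthropometric_table=config.anthropometric_table,
                        stiffness_mode=config.stiffness_mode)
                except Exception as exc:   # noqa: BLE001 - per-trial guard
                    skipped += 1
                    warnings.warn(
                        f"subject {si} session {sessions[sess]} trial {k} "
                        f"skipped: {exc}", stacklevel=2)
                    continue
                per_trial.append(res.metrics)
                trial_rows.append({"subject": si, "session": sessions[sess],
                                   "trial": k, **res.metrics.to_dict()})
            if not per_trial:
                raise RuntimeError(
                    f"analysis stage failed: no surviving trial for subject "
                    f"{si} in session {sessions[sess]}")
            mean_rows.append({"subject": si, "session": sessions[sess],
                              **average_trials(per_trial).to_dict()})

    trials = pd.DataFrame(trial_rows)
    subject_means = pd.DataFrame(mean_rows)
    pre_name, post_name = config.preset_pre, config.preset_post
    pre = subject_means[subject_means.session == pre_name].sort_values("subject")
    post = subject_means[subject_means.session == post_name].sort_values("subject")
    rows = []
    for var in DVJMetrics.field_names():
        a = pre[var].to_numpy()
        b = post[var].to_numpy()
        t, df, p, md = paired_t(a, b)
        rows.append({
            "variable": var,
            "units": METRIC_UNITS[var],
            "pre_mean": a.mean(), "pre_sd": a.std(ddof=1),
            "post_mean": b.mean(), "post_sd": b.std(ddof=1),
            "t": t, "df": df, "p": p,
            "pct_change": percent_change(a.mean(), b.mean()),
            "significant": p < config.alpha,
        })
    summary = pd.DataFrame(rows)
    report = StudyReport(config=config, trials=trials,
                         subject_means=subject_means, summary=summary,
                         n_skipped_trials=skipped)
    report.text = render_report(report)
    return report


def render_report(report: StudyReport) -> str:
    """Human-readable pre/post comparison table."""
    cfg = report.config
    buf = _io.StringIO()
    buf.write(f"dvjmech {__version__}  study report\n")
    buf.write(f"config sha256:{cfg.digest()}  seed={cfg.seed}  "
              f"n={cfg.n_subjects} subjects x {cfg.trials_per_subject} "
              f"trials  alpha={cfg.alpha}\n")
    buf.write(f"sessions: {cfg.preset_pre} vs {cfg.preset_post}; "
              f"dominant-leg ({cfg.side}) analysis\n\n")
    head = (f"{'variable':38s} {'units':9s} {'pre mean±SD':>18s} "
            f"{'post mean±SD':>18s} {'p':>8s} {'%chg':>7s}\n")
    buf.write(head)
    buf.write("-" * len(head) + "\n")
    for _, r in report.summary.iterrows():
        star = " *" if r["significant"] else "  "
        buf.write(f"{r['variable']:38s} {r['units']:9s} "
                  f"{r['pre_mean']:10.3f}±{r['pre_sd']:6.3f} "
                  f"{r['post_mean']:10.3f}±{r['post_sd']:6.3f} "
                  f"{r['p']:8.4f} {r['pct_change']:+6.1f}{star}\n")
    if report.n_skipped_trials:
        buf.write(f"\n{report.n_skipped_trials} trial(s) skipped\n")
    return buf.getvalue()


def write_report(report: StudyReport, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "config.yaml",
        "trials": out / "trials.csv",
        "subject_means": out / "subject_means.csv",
        "summary": out / "summary.csv",
        "report": out / "report.txt",
    }
    paths["config"].write_text(report.config.to_yaml())
    report.trials.to_csv(paths["trials"], index=False, float_format="%.6g")
    report.subject_means.to_csv(paths["subject_means"], index=False,
                                float_format="%.6g")
    report.summary.to_csv(paths["summary"], index=False, float_format="%.6g")
    paths["report"].write_text(report.text)
    return paths


# ---------------------------------------------------------------------------
# muscle-damage indicator summary
# ---------------------------------------------------------------------------

#: reliability-emulation parameters for the isometric-torque indicator:
#: between-subject mean/SD in Nm and the within-subject test-retest CV%.
TORQUE_RELIABILITY = dict(mean=300.0, between_sd=45.0, within_cv_pct=4.27)


def eimd_summary(seed: int = 0, n_subjects: int = 13,
                 alpha: float = 0.05) -> dict:
    """Reliability + time-course statistics of the damage indicators.

    Returns a dict with a tidy ``panel`` frame, per-indicator test
    results, percent changes of the means at 48 h, and the test-retest
    reliability of torque (simulated two-visit panel) and soreness (a
    floor-degenerate indicator: identically zero pre-exercise).
    """
    rng = np.random.default_rng(seed)
    panel = syn.generate_eimd_panel(
        syn.EIMDPanelParams(n_subjects=n_subjects, seed=seed))

    # reliability: two pre-exercise visits
    tr = TORQUE_RELIABILITY
    true_torque = rng.normal(tr["mean"], tr["between_sd"], n_subjects)
    within_sd = tr["within_cv_pct"] / 100 * tr["mean"] / 0.7979
    visits = true_torque[:, None] + rng.normal(0, within_sd, (n_subjects, 2))
    torque_rel = test_retest_reliability(visits[:, 0], visits[:, 1])
    soreness_rel = test_retest_reliability(np.zeros(n_subjects),
                                           np.zeros(n_subjects))

    def wide(ind):
        sub = panel[panel.indicator == ind]
        return sub.pivot(index="subject", columns="timepoint",
                         values="value")

    ipt = wide("IPT_pct")[["0h", "post", "24h", "48h"]]
    doms = wide("DOMS")[["0h", "24h", "48h"]]
    ck = wide("CK")[["0h", "48h"]]
    f_ipt = rm_anova_oneway(ipt.to_numpy())
    f_doms = rm_anova_oneway(doms.to_numpy())
    t_ck = paired_t(ck["0h"].to_numpy(), ck["48h"].to_numpy())
    return {
        "panel": panel,
        "reliability": {"IPT": torque_rel, "DOMS": soreness_rel},
        "rm_anova": {"IPT_pct": f_ipt, "DOMS": f_doms},
        "paired_t": {"CK": t_ck},
        "pct_change_48h": {
            "IPT_pct": percent_change(ipt["0h"].mean(), ipt["48h"].mean()),
            "CK": percent_change(ck["0h"].mean(), ck["48h"].mean()),
        },
        "alpha": alpha,
    }
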