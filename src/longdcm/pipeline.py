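"""End-to-end orchestration: cohort -> simulation -> preprocessing -> spectra
-> first-level inversions -> session PEB -> group PEB -> effect tables.

The run configuration is a validated schema (unknown keys rejected); a run
directory carries a manifest with versions, seeds and parameter defaults
sufficient to reproduce every output bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import networkx as nx
from pydantic import BaseModel, ConfigDict, Field

from . import io
from .cohort import (
    SCORE_TIMEPOINTS,
    SESSION_LABELS,
    GroupTruth,
    generate_scores,
    make_session_design,
    sample_group_truth,
)
from .errors import ComputeError, ValidationError
from .peb import PebOptions, PebPosterior, covariate_peb, peb_fit, peb_of_peb, reduce_gaussian, threshold_nonzero
from .preprocess import detrend_and_filter, discard_initial, regress_confounds
from .simulate import HemoParams, NoiseSpec, simulate_cohort_bold, sample_and_corrupt
from .spdcm import DcmPosterior, InvertOptions, ParamSpec, default_priors, invert
from .spectra import estimate_csd

logger = logging.getLogger(__name__)

MAX_SEED = 2**31 - 1


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectSpec(StrictModel):
    target: int
    source: int
    transient: float = 0.0
    sustained: float = 0.0


class CouplingSpec(StrictModel):
    target: int
    source: int
    gain: float


class CohortConfig(StrictModel):
    n_subjects: int = 8
    n_regions: int = 6
    sigma2: float = 0.05
    sigma3: float = 0.05
    effects: list[EffectSpec] = Field(
        default_factory=lambda: [
            EffectSpec(target=5, source=2, sustained=0.3),
            EffectSpec(target=5, source=1, sustained=0.2),
            EffectSpec(target=5, source=3, sustained=-0.2),
            EffectSpec(target=5, source=5, sustained=0.2),
            EffectSpec(target=2, source=2, transient=-0.2),
        ]
    )
    baseline_score: float = 20.0
    score_noise_sd: float = 0.5
    posture_couplings: list[CouplingSpec] = Field(
        default_factory=lambda: [
            CouplingSpec(target=5, source=2, gain=5.0),
            CouplingSpec(target=5, source=1, gain=3.0),
        ]
    )
    action_couplings: list[CouplingSpec] = Field(
        default_factory=lambda: [CouplingSpec(target=5, source=1, gain=4.0)]
    )

    def effect_spec(self) -> dict[tuple[int, int], tuple[float, float]]:
        return {(e.target, e.source): (e.transient, e.sustained) for e in self.effects}

    def coupling(self, which: str) -> dict[tuple[int, int], float]:
        entries = self.posture_couplings if which == "posture" else self.action_couplings
        return {(c.target, c.source): c.gain for c in entries}


class SimulationConfig(StrictModel):
    tr: float = 2.0
    n_volumes: int = 165
    dt: float = 0.05
    state_amp: float = 3e-5
    state_exp: float = 1.0
    obs_amp: float = 0.02
    obs_exp: float = 0.5
    drift_amp: float = 0.1
    confound_leak: float = 0.1

    def noise(self) -> NoiseSpec:
        return NoiseSpec(
            state_amp=self.state_amp,
            state_exp=self.state_exp,
            obs_amp=self.obs_amp,
            obs_exp=self.obs_exp,
            drift_amp=self.drift_amp,
        )


class PreprocessConfig(StrictModel):
    n_discard: int = 5
    highpass_hz: float = 0.009
    lowpass_hz: float | None = None
    regress_confounds: bool = True


class CsdConfig(StrictModel):
    order: int = 4  # smooth MAR spectra for ~160-sample sessions
    fmin: float = 0.01
    fmax: float = 0.25
    n_freqs: int = 16


class SpdcmConfig(StrictModel):
    max_iter: int = 128
    tol: float = 0.01

    def options(self) -> InvertOptions:
        return InvertOptions(max_iter=self.max_iter, tol=self.tol)


class PebConfig(StrictModel):
    level: float = 0.95
    downward_passes: int = 1
    beta_prior_var: float = 1.0
    gamma_mean: float = 4.0
    gamma_var: float = 1.0

    def options(self) -> PebOptions:
        return PebOptions(
            beta_prior_var=self.beta_prior_var,
            gamma_mean=self.gamma_mean,
            gamma_var=self.gamma_var,
        )


class RunConfig(StrictModel):
    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    csd: CsdConfig = Field(default_factory=CsdConfig)
    spdcm: SpdcmConfig = Field(default_factory=SpdcmConfig)
    peb: PebConfig = Field(default_factory=PebConfig)
    write_intermediates: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML run configuration, validating strictly."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return RunConfig.model_validate(payload)


@dataclass
class RunResult:
    config: RunConfig
    truth: GroupTruth
    scores: dict[str, pd.DataFrame]
    posteriors: list[list[DcmPosterior]]  # [subject][session]
    session_pebs: list[PebPosterior]
    group_peb: PebPosterior
    covariate_pebs: dict[str, PebPosterior]
    effect_tables: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)
    outdir: Path | None = None


def _stage(name: str, subject=None, session=None):
    where = name
    if subject is not None:
        where += f" subject={subject}"
    if session is not None:
        where += f" session={session}"
    return where


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full analysis on a synthetic cohort.

    Stages: ground-truth generation, forward BOLD simulation for every
    session, acquisition corruption, preprocessing, cross-spectral
    estimation, spectral-DCM inversion per session, per-subject session PEB
    with one empirical-prior downward pass, group PEB-of-PEB, covariate PEBs
    for the two symptom scores, and 95% credible-interval effect tables.
    """
    rng = np.random.default_rng(config.seed)

    def next_seed() -> int:
        return int(rng.integers(MAX_SEED))

    cc, sc = config.cohort, config.simulation
    stage = "cohort"
    try:
        truth = sample_group_truth(
            n_subjects=cc.n_subjects,
            n_regions=cc.n_regions,
            effect_spec=cc.effect_spec(),
            sigma2=cc.sigma2,
            sigma3=cc.sigma3,
            seed=next_seed(),
            score_coupling=cc.coupling("posture"),
        )
        scores = {
            "posture": generate_scores(
                truth, cc.baseline_score, cc.score_noise_sd, next_seed(),
                score_coupling=cc.coupling("posture"),
            ),
            "action": generate_scores(
                truth, cc.baseline_score, cc.score_noise_sd, next_seed(),
                score_coupling=cc.coupling("action"),
            ),
        }

        stage = "simulate"
        J, S = truth.n_subjects, truth.n_sessions
        a_list = [truth.theta[j, s] for j in range(J) for s in range(S)]
        duration = sc.tr * sc.n_volumes
        bold = simulate_cohort_bold(
            a_list, sc.noise(), duration, sc.dt, next_seed()
        )

        spec = ParamSpec(cc.n_regions)
        freqs = np.geomspace(config.csd.fmin, config.csd.fmax, config.csd.n_freqs)
        posteriors: list[list[DcmPosterior]] = []
        series_store, confound_store = [], []
        for j in range(J):
            row = []
            for s in range(S):
                stage = _stage("acquire", j, s)
                ser, conf = sample_and_corrupt(
                    bold[j * S + s], sc.tr, sc.n_volumes, sc.noise(),
                    seed=next_seed(), dt=sc.dt,
                    confound_leak=sc.confound_leak,
                    region_names=truth.region_names,
                )
                stage = _stage("preprocess", j, s)
                pp = discard_initial(ser, config.preprocess.n_discard)
                conf_pp = conf.iloc[config.preprocess.n_discard :].reset_index(drop=True)
                if config.preprocess.regress_confounds:
                    pp = regress_confounds(pp, conf_pp)
                pp = detrend_and_filter(
                    pp, config.preprocess.highpass_hz, config.preprocess.lowpass_hz
                )
                stage = _stage("csd", j, s)
                sd = estimate_csd(pp, order=config.csd.order, freqs=freqs)
                stage = _stage("spdcm", j, s)
                post = invert(sd, default_priors(spec), config.spdcm.options())
                if not post.meta.get("converged", False):
                    logger.warning(
                        "inversion not converged: subject %d session %d", j, s
                    )
                row.append(post)
                series_store.append((j, s, ser, pp))
                confound_store.append((j, s, conf))
            posteriors.append(row)

        stage = "peb-sessions"
        design = make_session_design(S)
        peb_opts = config.peb.options()
        carried = spec.a_indices
        session_pebs = []
        final_posteriors = [list(row) for row in posteriors]
        for j in range(J):
            peb_j, _ = peb_fit(posteriors[j], design, carried=carried, opts=peb_opts)
            session_pebs.append(peb_j)

        stage = "peb-downward"
        for _ in range(config.peb.downward_passes):
            for j in range(J):
                _, empirical = peb_fit(
                    final_posteriors[j], design, carried=carried, opts=peb_opts
                )
                updated = []
                for s, post in enumerate(final_posteriors[j]):
                    m_c, c_c = reduce_gaussian(
                        post.mean[carried],
                        post.cov[np.ix_(carried, carried)],
                        post.prior.mean[carried],
                        np.diag(post.prior.variance[carried]),
                        empirical[s][0],
                        empirical[s][1],
                    )
                    mean = np.array(post.mean, copy=True)
                    cov = np.array(post.cov, copy=True)
                    mean[carried] = m_c
                    cov[np.ix_(carried, carried)] = c_c
                    updated.append(
                        SimpleNamespace(mean=mean, cov=cov, source=post)
                    )
                final_posteriors[j] = updated
            session_pebs = []
            for j in range(J):
                peb_j, _ = peb_fit(
                    final_posteriors[j], design, carried=carried, opts=peb_opts,
                    param_labels=[spec.names()[i] for i in carried],
                )
                session_pebs.append(peb_j)

        stage = "peb-group"
        group_peb = peb_of_peb(session_pebs, opts=peb_opts)

        stage = "peb-covariate"
        tps = list(SCORE_TIMEPOINTS)
        covariate_pebs = {}
        for which in ("posture", "action"):
            subject_posts = {
                f"S{j + 1}": {
                    tp: final_posteriors[j][SCORE_TIMEPOINTS[tp]] for tp in tps
                }
                for j in range(J)
            }
            covariate_pebs[which] = covariate_peb(
                subject_posts,
                scores[which],
                score_name=which,
                carried=carried,
                opts=peb_opts,
                param_labels=[spec.names()[i] for i in carried],
            )

        stage = "report"
        effect_tables = {
            "sessions": threshold_nonzero(
                group_peb, config.peb.level, truth.region_names
            )
        }
        for which, peb in covariate_pebs.items():
            effect_tables[f"covariate_{which}"] = threshold_nonzero(
                peb, config.peb.level, truth.region_names
            )
    except Exception as err:
        if isinstance(err, (ValidationError, ComputeError)):
            raise type(err)(f"[stage {stage}] {err}") from err
        raise ComputeError(f"[stage {stage}] {err}") from err

    manifest = {
        "package": "longdcm",
        "config": config.model_dump(),
        "session_labels": SESSION_LABELS,
        "region_names": truth.region_names,
        "bold_constants": HemoParams().bold_constants(),
        "hemodynamics": HemoParams().__dict__,
        "frequency_grid_hz": list(map(float, freqs)),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "converged": [
            [bool(p.meta.get("converged", False)) for p in row] for row in posteriors
        ],
    }

    result = RunResult(
        config=config,
        truth=truth,
        scores=scores,
        posteriors=posteriors,
        session_pebs=session_pebs,
        group_peb=group_peb,
        covariate_pebs=covariate_pebs,
        effect_tables=effect_tables,
        manifest=manifest,
        outdir=Path(outdir) if outdir else None,
    )
    if outdir is not None:
        _write_run(result, Path(outdir), series_store, confound_store)
    return result


def _write_run(result: RunResult, outdir: Path, series_store, confound_store):
    outdir.mkdir(parents=True, exist_ok=True)
    io.save_truth(result.truth, outdir / "truth.h5")
    for which, table in result.scores.items():
        table.to_csv(outdir / f"scores_{which}.csv", index=False, float_format="%.10g")
    io.save_peb(result.group_peb, outdir / "peb_group.h5")
    files = ["truth.h5", "scores_posture.csv", "scores_action.csv", "peb_group.h5"]
    for which, peb in result.covariate_pebs.items():
        io.save_peb(peb, outdir / f"peb_covariate_{which}.h5")
        files.append(f"peb_covariate_{which}.h5")
    for j, peb in enumerate(result.session_pebs):
        io.save_peb(peb, outdir / f"sub-{j + 1:02d}_peb.h5")
        files.append(f"sub-{j + 1:02d}_peb.h5")
    if result.config.write_intermediates:
        for j, s, raw, pp in series_store:
            sub = outdir / f"sub-{j + 1:02d}"
            sub.mkdir(exist_ok=True)
            label = SESSION_LABELS[s]
            io.write_series(raw, sub / f"ses-{label}_raw.tsv", {"stage": "raw"})
            io.write_series(pp, sub / f"ses-{label}_clean.tsv", {"stage": "preprocessed"})
            files += [f"sub-{j + 1:02d}/ses-{label}_raw.tsv", f"sub-{j + 1:02d}/ses-{label}_clean.tsv"]
        for j, s, conf in confound_store:
            sub = outdir / f"sub-{j + 1:02d}"
            label = SESSION_LABELS[s]
            io.write_confounds(conf, sub / f"ses-{label}_confounds.tsv")
            files.append(f"sub-{j + 1:02d}/ses-{label}_confounds.tsv")
        for j, row in enumerate(result.posteriors):
            sub = outdir / f"sub-{j + 1:02d}"
            for s, post in enumerate(row):
                name = f"ses-{SESSION_LABELS[s]}_posterior.h5"
                io.save_posterior(post, sub / name)
                files.append(f"sub-{j + 1:02d}/{name}")
    for name, table in result.effect_tables.items():
        path = outdir / f"effects_{name}.csv"
        cols = ["source", "target", "effect", "mean", "sd", "lo95", "hi95", "survives"]
        table[cols].to_csv(path, index=False, float_format="%.10g")
        files.append(path.name)
        for effect in table["effect"].unique():
            g = io.effect_graph(table, effect)
            if g.number_of_edges() == 0:
                continue
            stem = f"graph_{name}_{effect.replace(':', '_')}"
            nx.write_graphml(g, outdir / f"{stem}.graphml")
            io.write_dot(g, outdir / f"{stem}.dot")
            files += [f"{stem}.graphml", f"{stem}.dot"]
    result.manifest["files"] = sorted(files)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )


def compare_truth_dir(run_dir: str | Path, truth_path: str | Path | None = None) -> dict:
    """Recovery report computed from a written run directory."""
    run_dir = Path(run_dir)
    truth = io.load_truth(truth_path or run_dir / "truth.h5")
    group = io.load_peb(run_dir / "peb_group.h5")
    n = truth.n_regions
    if len(group.meta["level1_params"]) != n * n:
        raise ValidationError("truth does not match the run's region count")
    report = _recovery_report(group, truth)
    (run_dir / "recovery.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def compare_truth(result: RunResult, truth: GroupTruth | None = None) -> dict:
    """Recovery report: sign agreement, interval coverage, RMSE vs truth."""
    truth = truth or result.truth
    if truth.n_regions != result.truth.n_regions:
        raise ValidationError("truth does not match the run's region count")
    report = _recovery_report(result.group_peb, truth)
    if result.outdir is not None:
        (result.outdir / "recovery.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def _recovery_report(group: PebPosterior, truth: GroupTruth) -> dict:
    effects1 = group.meta["level1_effects"]
    c = len(group.meta["level1_params"])
    means = group.beta_mean.reshape(len(effects1), c)
    sds = group.beta_sd().reshape(len(effects1), c)
    report: dict = {"effects": {}}
    for e, eff in enumerate(effects1):
        true_row = truth.beta3[e]
        est, sd = means[e], sds[e]
        lo, hi = est - 1.959964 * sd, est + 1.959964 * sd
        covered = float(np.mean((true_row >= lo) & (true_row <= hi)))
        planted = np.abs(true_row) > 1e-12
        entry = {
            "rmse": float(np.sqrt(np.mean((est - true_row) ** 2))),
            "coverage95": covered,
        }
        if eff != "baseline":
            survivors = (lo > 0) | (hi < 0)
            if planted.any():
                entry["sign_agreement"] = float(
                    np.mean(np.sign(est[planted]) == np.sign(true_row[planted]))
                )
                entry["planted_survival"] = float(np.mean(survivors[planted]))
            entry["false_positive_rate"] = float(np.mean(survivors[~planted]))
        report["effects"][eff] = entry
    return report
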