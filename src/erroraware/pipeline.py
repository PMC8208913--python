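"""End-to-end orchestration: simulate -> filter -> behavioral GLMs ->
preprocess -> EEG GLMs -> decoding -> ITPC -> coupling, with a manifest
that makes the run bit-reproducible and a report comparing recovered
estimates against the simulation ground truth.

Each subject receives an independent RNG substream spawned from the master
seed, so results do not depend on execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st

from . import __version__
from .simulate import TaskDesign, GroundTruth, simulate_subject
from .montage import ring_montage
from . import behavior as bh
from . import preprocess as pp
from . import eeg_glm as eg
from . import mvpa
from . import itpc as itpc_mod
from . import coupling as cp
from .io import write_json, write_trial_table

__all__ = ["PipelineConfig", "run_pipeline", "PipelineRun"]


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 5
    design: TaskDesign = field(default_factory=lambda: TaskDesign())
    truth: GroundTruth = field(default_factory=lambda: GroundTruth())
    seed: int = 0
    eeg_decim: int = 2
    artifact_rejection: bool = True
    mvpa_folds: int = 10
    mvpa_permutations: int = 0     # 0 skips the permutation test
    itpc_electrode: str = "Cz"
    probe_freq_hz: float = 9.0
    ern_window_s: tuple[float, float] = (0.02, 0.12)
    pe_window_s: tuple[float, float] = (0.15, 0.35)


@dataclass
class PipelineRun:
    config: PipelineConfig
    results: dict
    manifest: dict


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineRun:
    """Run every stage on a fresh simulated cohort."""
    cfg = config or PipelineConfig()
    montage = ring_montage()
    ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in ss.spawn(cfg.n_subjects)]
    mvpa_cfg = mvpa.DecodingConfig(n_folds=cfg.mvpa_folds, seed=cfg.seed)

    trial_tables, glm1_fits, glm2_fits = [], [], []
    decode_curves, decode_times = [], None
    itpc_diffs = []
    pes_aware_stats = {"rt_aware": [], "rt_unaware": []}
    exclusions = []

    for si, sub_seed in enumerate(subject_seeds):
        truth = replace(cfg.truth, seed=sub_seed)
        trials, epochs = simulate_subject(cfg.design, truth, seed=sub_seed,
                                          with_eeg=True, montage=montage)
        trials = bh.add_previous_trial_columns(trials)
        filtered, excl = bh.filter_trials(trials)
        exclusions.append(excl)
        trial_tables.append((trials, filtered))

        epochs = pp.rereference_common_average(epochs)
        if cfg.artifact_rejection:
            epochs, _, _ = pp.reject_joint_probability(epochs)
        epochs = pp.baseline_correct(epochs)
        # behavioral exclusions propagate to the EEG analyses
        keep = np.isin(epochs.trial_index, filtered["trial_nr"].to_numpy())
        epochs = epochs.select_trials(keep)

        d1 = eg.build_eeg_design(filtered, model=1)
        glm1_fits.append(eg.fit_mass_univariate(epochs, d1,
                                                decim=cfg.eeg_decim))
        d2 = eg.build_eeg_design(filtered, model=2)
        glm2_fits.append(eg.fit_mass_univariate(epochs, d2,
                                                decim=cfg.eeg_decim))

        err_mask = np.isin(
            epochs.trial_index,
            filtered.loc[filtered["awareness"].isin(
                ["aware_error", "unaware_error"]), "trial_nr"])
        err_epochs = epochs.select_trials(err_mask)
        lab = filtered.set_index("trial_nr").loc[
            err_epochs.trial_index, "awareness"].to_numpy()
        feats, ftimes = mvpa.prepare_features(err_epochs, mvpa_cfg)
        if min(np.sum(lab == "aware_error"),
               np.sum(lab == "unaware_error")) >= mvpa_cfg.min_predict_trials:
            res = mvpa.decode_timecourse(
                feats, lab, mvpa_cfg, np.random.default_rng(sub_seed))
            decode_curves.append(res.accuracy)
            decode_times = ftimes

        aware_ep = err_epochs.select_trials(lab == "aware_error")
        unaware_ep = err_epochs.select_trials(lab == "unaware_error")
        if aware_ep.n_trials >= 5 and unaware_ep.n_trials >= 5:
            ph_a, fr, tt, valid = itpc_mod.tf_phase(aware_ep,
                                                    cfg.itpc_electrode)
            ph_u, *_ = itpc_mod.tf_phase(unaware_ep, cfg.itpc_electrode)
            map_a = itpc_mod.compute_itpc(ph_a, fr, tt, valid=valid)
            map_u = itpc_mod.compute_itpc(ph_u, fr, tt, valid=valid)
            itpc_diffs.append((map_a, map_u))

        for variant in ("aware", "unaware"):
            fit = bh.fit_rt_glm(filtered, posterror=variant)
            pes_aware_stats[f"rt_{variant}"].append(fit)

    # ---- group level -----------------------------------------------------
    results: dict = {}
    raw_tables = [t for t, _ in trial_tables]
    filt_tables = [f for _, f in trial_tables]
    results["behavior_rt"] = bh.fit_group(filt_tables, model="rt")
    results["behavior_acc"] = bh.fit_group(filt_tables, model="accuracy")
    for variant in ("aware", "unaware"):
        fits = [f for f in pes_aware_stats[f"rt_{variant}"] if f.ok]
        tvals = pd.DataFrame({i: f.tvalues for i, f in enumerate(fits)}).T
        results[f"behavior_rt_post_{variant}"] = bh.group_test(tvals)

    group1 = eg.group_stats(glm1_fits)
    group2 = eg.group_stats(glm2_fits)
    target = eg.choose_target_electrode(group1, "error")
    results["eeg_glm1"] = group1
    results["eeg_glm2"] = group2
    results["target_electrode"] = target
    results["ern_peak"] = eg.extract_peak(group1, "error", cfg.ern_window_s,
                                          target, polarity="neg")
    results["pe_peak"] = eg.extract_peak(group1, "error", cfg.pe_window_s,
                                         target, polarity="pos")
    results["awareness_ern_peak"] = eg.extract_peak(
        group2, "error_awareness", cfg.ern_window_s, target, polarity="neg")
    results["awareness_pe_peak"] = eg.extract_peak(
        group2, "error_awareness", cfg.pe_window_s, target, polarity="pos")

    if decode_curves:
        curve = np.mean(decode_curves, axis=0)
        results["decoding"] = {
            "group_accuracy": curve, "times": decode_times,
            "peak_accuracy": float(curve.max()),
            "peak_latency_s": float(decode_times[int(np.argmax(curve))]),
            "n_subjects": len(decode_curves),
        }

    if itpc_diffs:
        zd = np.mean([a.itpc_z - u.itpc_z for a, u in itpc_diffs], axis=0)
        a0 = itpc_diffs[0][0]
        r_aw = group2.regressor_index("error_awareness")
        ch = group2.ch_names.index(cfg.itpc_electrode)
        fi = int(np.argmin(np.abs(a0.freqs - cfg.probe_freq_hz)))
        mask = a0.valid[fi]
        reg = np.interp(a0.times, group2.times, group2.b[r_aw, ch])
        if np.std(zd[fi, mask]) > 0 and np.std(reg[mask]) > 0:
            r, p = st.pearsonr(reg[mask], zd[fi, mask])
        else:
            r = p = np.nan
        results["itpc"] = {"z_diff_group": zd, "freqs": a0.freqs,
                           "times": a0.times, "valid": a0.valid,
                           "probe_freq_hz": float(a0.freqs[fi]),
                           "correlation_r": r, "correlation_p": p}

    # across-subject ERN/Pe-vs-PES coupling
    aw_fits = pes_aware_stats["rt_aware"]
    pes_betas = np.array([f.betas.get("prev_accuracy", np.nan)
                          if f.ok else np.nan for f in aw_fits])
    r_aw = group2.regressor_index("error_awareness")
    ch = group2.ch_names.index(target)
    t_ern = np.argmin(np.abs(group2.times
                             - results["awareness_ern_peak"]["latency_s"]))
    t_pe = np.argmin(np.abs(group2.times
                            - results["awareness_pe_peak"]["latency_s"]))
    ern_betas = np.array([f.beta[r_aw, ch, t_ern] for f in glm2_fits])
    pe_betas = np.array([f.beta[r_aw, ch, t_pe] for f in glm2_fits])
    try:
        results["coupling_ern_pes"] = cp.group_ern_pes_correlation(
            ern_betas, pes_betas)
        results["coupling_pe_pes"] = cp.group_ern_pes_correlation(
            pe_betas, pes_betas)
    except ValueError:
        pass

    manifest = _build_manifest(cfg, subject_seeds, exclusions, results,
                               raw_tables)
    run = PipelineRun(config=cfg, results=results, manifest=manifest)
    if out_dir is not None:
        _persist(run, raw_tables, Path(out_dir))
    return run


def _build_manifest(cfg, subject_seeds, exclusions, results, raw_tables):
    truth_snapshot = asdict(cfg.truth)
    hashes = {
        "trial_tables": _hash(*[
            pd.util.hash_pandas_object(t.astype(str)).to_numpy()
            for t in raw_tables]),
        "eeg_glm1_b": _hash(results["eeg_glm1"].b),
        "eeg_glm2_b": _hash(results["eeg_glm2"].b),
        "behavior_rt_group": _hash(
            results["behavior_rt"].group["t"].to_numpy()),
    }
    if "decoding" in results:
        hashes["decoding_curve"] = _hash(results["decoding"]
                                         ["group_accuracy"])
    return {
        "version": __version__,
        "seed": cfg.seed,
        "subject_seeds": subject_seeds,
        "config": {"n_subjects": cfg.n_subjects,
                   "design": asdict(cfg.design),
                   "truth": truth_snapshot,
                   "eeg_decim": cfg.eeg_decim,
                   "mvpa_folds": cfg.mvpa_folds},
        "exclusions": exclusions,
        "hashes": hashes,
    }


def _recovery_table(run: PipelineRun) -> pd.DataFrame:
    """Truth vs estimate for the headline injected effects."""
    cfg, res = run.config, run.results
    rows = []
    grt = res["behavior_rt"].group
    for reg, truth_val in cfg.truth.rt_betas.items():
        if reg in ("intercept",) or reg not in grt.index:
            continue
        est = res["behavior_rt"].subject_betas[reg].mean()
        rows.append({"quantity": f"rt_beta[{reg}]", "truth": truth_val,
                     "estimate": est, "bias": est - truth_val})
    rows.append({"quantity": "awareness_pe_peak_b",
                 "truth": cfg.truth.pe_gain,
                 "estimate": res["awareness_pe_peak"]["b"],
                 "bias": res["awareness_pe_peak"]["b"] - cfg.truth.pe_gain})
    rows.append({"quantity": "awareness_ern_peak_b",
                 "truth": -cfg.truth.ern_gain,
                 "estimate": res["awareness_ern_peak"]["b"],
                 "bias": res["awareness_ern_peak"]["b"]
                 + cfg.truth.ern_gain})
    return pd.DataFrame(rows)


def _persist(run: PipelineRun, raw_tables, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_json(run.manifest, out / "manifest.json")
    for i, t in enumerate(raw_tables):
        write_trial_table(t, out / f"subject{i:02d}_trials.tsv")
    res = run.results
    res["behavior_rt"].group.to_csv(out / "behavior_rt_group.tsv", sep="\t")
    res["behavior_acc"].group.to_csv(out / "behavior_acc_group.tsv",
                                     sep="\t")
    lines = ["# Pipeline report", "",
             f"Subjects: {run.config.n_subjects}; seed: {run.config.seed}",
             "", "## Peaks", ""]
    for key in ("ern_peak", "pe_peak", "awareness_ern_peak",
                "awareness_pe_peak"):
        pk = res[key]
        lines.append(f"- {key}: {pk['electrode']} at "
                     f"{pk['latency_s'] * 1000:.0f} ms, b = {pk['b']:.2f}, "
                     f"corrected p = {pk['p_corrected']:.3g}")
    if "decoding" in res:
        d = res["decoding"]
        lines.append(f"- decoding peak: {d['peak_accuracy'] * 100:.1f}% at "
                     f"{d['peak_latency_s'] * 1000:.0f} ms")
    lines += ["", "## Recovery", "",
              _recovery_table(run).to_markdown(index=False), "",
              "Note: the common-average reference removes the spatial "
              "mean of the injected topography, attenuating the EEG "
              "awareness gains relative to their nominal values, and "
              "window-extremum extraction is max-biased in small "
              "cohorts; behavioral betas are directly comparable."]
    (out / "report.md").write_text("\n".join(lines))
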