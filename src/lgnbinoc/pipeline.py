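"""End-to-end orchestration: screen -> autocorrelate -> decompose -> test.

The analysis funnel mirrors the study's reporting: units recorded ->
retained after the mean-rate filter -> stability-trimmed -> responsive ->
significantly modulated, with every exclusion logged with its reason and
the counts reconciled in the bundle manifest.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binocular_stats as bs
from . import classification as cls
from . import io_model, spectral, spike_density, stability
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class AnalysisBundle:
    modulation_records: pd.DataFrame
    population_summaries: list
    stability_report: pd.DataFrame
    spectral_report: pd.DataFrame
    classification: pd.DataFrame
    proportion_trend: dict | None
    crf: dict
    manifest: dict
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.modulation_records.to_csv(out / "modulation_records.csv", index=False)
        self.stability_report.to_csv(out / "stability_report.csv", index=False)
        self.spectral_report.to_csv(out / "spectral_report.csv", index=False)
        self.classification.to_csv(out / "classification.csv", index=False)
        summary = {
            "populations": [vars(s) for s in self.population_summaries],
            "proportion_trend": self.proportion_trend,
            "crf": {k: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                        for kk, vv in v.items()} for k, v in self.crf.items()},
            "manifest": self.manifest,
            "errors": self.errors,
        }
        with open(out / "population_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)


def _unit_trials(trials: io_model.TrialTable, unit_id) -> pd.DataFrame:
    """Trials belonging to a unit, in presentation order.

    A ``unit_id`` column in the trial table assigns trials to units
    (one-session-per-unit recordings); without it all trials are shared.
    """
    df = trials.df
    if "unit_id" in df.columns:
        return df[df["unit_id"] == unit_id].reset_index(drop=True)
    return df


def _condition_key(row) -> tuple:
    if row["is_blank"]:
        return ("blank", "", "")
    dom = io_model.bin_contrast(float(row["dom_contrast"])).label
    nd = io_model.bin_contrast(float(row["nondom_contrast"])).label
    return (str(row["chromatic_axis"]), dom, nd)


def _binaries_for(spikes: io_model.SpikeTable, unit_id, trial_ids,
                  durations) -> np.ndarray:
    n = int(round(max(durations)))
    X = np.zeros((len(trial_ids), n), dtype=np.int8)
    sub = spikes.df[spikes.df["unit_id"] == unit_id]
    grouped = dict(tuple(sub.groupby("trial_id")))
    for i, (tr, dur) in enumerate(zip(trial_ids, durations)):
        g = grouped.get(tr)
        if g is None:
            continue
        X[i] = io_model.binarize(g["spike_time_ms"].to_numpy(dtype=float),
                                 (0.0, n))
    return X


def run_analysis(config: PipelineConfig, spikes: io_model.SpikeTable,
                 trials: io_model.TrialTable) -> AnalysisBundle:
    """Run the full analysis pipeline on loaded tables."""
    io_model.validate_pair(spikes, trials)
    kernel = spike_density.psp_kernel(config.tau_g_ms, config.tau_d_ms)
    errors: list = []
    exclusions: dict = {"low_rate": [], "unstable": [], "no_spikes": []}

    retained_units, low_rate = spike_density.mean_rate_filter(
        spikes, threshold=config.rate_threshold, window=config.count_window,
        kernel=kernel)
    exclusions["low_rate"] = list(low_rate)

    stab_rows, spec_rows, mod_rows, class_rows = [], [], [], []
    unit_condition_f1: dict = {}
    unit_classes: dict = {}

    for unit in retained_units:
        utr = _unit_trials(trials, unit)
        order = list(utr["trial_id"])
        try:
            rep = stability.screen_unit(
                spikes, unit, order, window=config.count_window,
                smooth_window=config.smooth_window,
                penalty=config.stability_penalty,
                min_segment=config.min_segment,
                policy=config.stability_policy, mad_k=config.mad_k)
            retained_ids = rep.retained_trial_ids
        except ValueError as exc:
            exclusions["unstable"].append(unit)
            errors.append(f"unit {unit}: {exc}")
            continue
        if unit in config.manual_overrides:
            spans = config.manual_overrides[unit]
            keep = sorted({i for a, b in spans for i in range(a, b)})
            retained_ids = [order[i] for i in keep if i < len(order)]
        stab_rows.append(dict(
            unit_id=unit, n_trials=rep.n_trials,
            change_points=";".join(map(str, rep.change_points)),
            segment_means=";".join(f"{m:.3f}" for m in rep.segment_means),
            n_retained=len(retained_ids),
        ))
        kept = utr[utr["trial_id"].isin(set(retained_ids))]

        # --- per-trial autocorrelations and spectra, batched per unit
        # Trailing zeros do not change the linear coincidence
        # autocorrelation, so trials of slightly different duration share
        # one matrix and a single spectral decomposition per unit.
        keys = [_condition_key(r) for _, r in kept.iterrows()]
        nonblank = kept[~kept["is_blank"].astype(bool)]
        unit_drift = (float(nonblank["drift_freq_hz"].median())
                      if not nonblank.empty else 4.0)
        X = _binaries_for(spikes, unit, list(kept["trial_id"]),
                          kept["stim_duration_ms"].to_numpy(dtype=float))
        from .phase_response import autocorr_matrix
        V, _ = autocorr_matrix(X)
        valid = ~np.isnan(V).any(axis=1)
        freq_need = sorted({unit_drift, 2 * unit_drift}
                           | set(nonblank["drift_freq_hz"].astype(float))
                           | {2 * f for f in nonblank["drift_freq_hz"].astype(float)})
        powers: dict = {}
        if valid.any():
            powers = spectral.irasa_at_frequencies(V[valid], freq_need,
                                                   hset=config.hset)
        # map back to full trial indexing
        pos = np.full(len(kept), -1)
        pos[valid] = np.arange(valid.sum())

        def _f1_for(mask: np.ndarray, f: float) -> spectral.F1Response:
            rows = pos[mask]
            good = rows[rows >= 0]
            if f not in powers or len(good) == 0:
                return spectral.F1Response(np.empty(0), np.empty(0), f,
                                           int(mask.sum()))
            osc, frac = powers[f]
            return spectral.F1Response(np.asarray(osc)[good],
                                       np.asarray(frac)[good], f,
                                       int(mask.sum() - len(good)))

        cond_f1: dict = {}
        blank_f1 = None
        for key in sorted(set(keys), key=str):
            mask = np.array([k == key for k in keys])
            if key[0] == "blank":
                blank_f1 = _f1_for(mask, unit_drift)
                continue
            drift = float(kept.loc[mask, "drift_freq_hz"].iloc[0])
            cond_f1[key] = _f1_for(mask, drift)
            if key[0] == "L-M":  # frequency-doubling probe for classification
                cond_f1[key + ("F2",)] = _f1_for(mask, 2 * drift)
        unit_condition_f1[unit] = (cond_f1, blank_f1)

        responsive_conditions = set()
        for key, resp in cond_f1.items():
            if len(key) == 4:  # F2 probe, not a test condition
                continue
            res = spectral.responsiveness_test(
                resp, blank_f1, alpha=config.alpha,
                paired=config.paired_criterion2)
            spec_rows.append(dict(
                unit_id=unit, chromatic_axis=key[0], dom_bin=key[1],
                nondom_bin=key[2], n_trials=resp.n_trials,
                n_zero_spike=resp.n_excluded,
                mean_oscillatory=resp.mean,
                mean_fractal=float(np.mean(resp.fractal)) if resp.n_trials else np.nan,
                p_versus_blank=res.p_versus_blank,
                p_osc_versus_fractal=res.p_osc_versus_fractal,
                responsive=res.responsive, status=res.status))
            if res.responsive:
                responsive_conditions.add(key)

        # --- classification inputs (dominant-eye chromatic responses)
        f1_by_axis = {}
        rg_f2 = float("nan")
        for axis in ("L+M", "L-M", "S"):
            k = [key for key in cond_f1 if len(key) == 3 and key[0] == axis
                 and key[2] == "zero"]
            if k:
                f1_by_axis[axis] = float(np.mean(
                    [cond_f1[key].mean for key in k]))
        k2 = [key for key in cond_f1 if len(key) == 4 and key[0] == "L-M"
              and key[2] == "zero"]
        if k2:
            rg_f2 = float(np.mean([cond_f1[key].mean for key in k2]))
        sig = cls.chromatic_signature(unit, f1_by_axis, rg_f2)
        # CRF from monocular achromatic conditions
        crf_pts = {}
        for key, resp in cond_f1.items():
            if (len(key) == 3 and key[0] == "achromatic" and key[2] == "zero"
                    and key[1] != "unbinned"):
                crf_pts[io_model.bin_by_label(key[1]).representative] = resp.mean
        if blank_f1 is not None and blank_f1.n_trials:
            crf_pts.setdefault(0.0, max(blank_f1.mean, 0.0))
        crf_shape = None
        if len(crf_pts) >= 4:
            try:
                crf_shape = cls.fit_crf(sorted(crf_pts),
                                        [crf_pts[c] for c in sorted(crf_pts)],
                                        unit_id=unit)
            except ValueError:
                crf_shape = None
        label = cls.classify_pmk(sig, crf_shape)
        unit_classes[unit] = label.label
        class_rows.append(dict(
            unit_id=unit, label=label.label, confidence=label.confidence,
            s_index=label.s_index, rg_index=label.rg_index,
            doubling_index=label.doubling_index,
            saturation_index=label.saturation_index,
            c50=crf_shape.c50 if crf_shape and crf_shape.fitted else np.nan,
            hill_n=crf_shape.hill_n if crf_shape and crf_shape.fitted else np.nan,
            rules="|".join(label.rules_fired)))

        # --- modulation records: binocular vs matched monocular
        for key, resp in cond_f1.items():
            if len(key) != 3 or key[0] != "achromatic":
                continue
            axis, dom, nd = key
            if nd in ("zero", "unbinned") or dom == "unbinned":
                continue
            mono_key = (axis, dom, "zero")
            if mono_key not in cond_f1:
                continue
            mono = cond_f1[mono_key]
            if mono.n_trials < config.min_trials or resp.n_trials < config.min_trials:
                continue
            if config.require_responsive and mono_key not in responsive_conditions:
                continue
            if mono.mean <= 0:
                errors.append(f"unit {unit} {key}: non-positive monocular mean")
                continue
            pd_ = bs.percent_modulation(mono.mean, resp.mean)
            ukey = zlib.crc32(f"{unit}|{dom}|{nd}".encode()) & 0x7FFFFFFF
            sh = bs.shuffle_null(resp.oscillatory, mono.oscillatory,
                                 n_shuffles=config.n_shuffles,
                                 quantile=config.quantile,
                                 rng=config.rng_for("shuffle", ukey),
                                 method=config.shuffle_method)
            sh_rel = bs.shuffle_null(resp.oscillatory, mono.oscillatory,
                                     n_shuffles=config.n_shuffles,
                                     quantile=config.quantile_relaxed,
                                     rng=config.rng_for("shuffle_relaxed", ukey),
                                     method=config.shuffle_method)
            mod_rows.append(dict(
                unit_id=unit, dom_bin=dom, nondom_bin=nd,
                mono_f1_mean=mono.mean, binoc_f1_mean=resp.mean,
                percent_diff=pd_, roc_auc=sh.auc,
                roc_significant=sh.significant, direction=sh.direction,
                relaxed_significant=sh_rel.significant,
                relaxed_direction=sh_rel.direction,
                n_mono=mono.n_trials, n_binoc=resp.n_trials))

    mod_df = pd.DataFrame(mod_rows, columns=[
        "unit_id", "dom_bin", "nondom_bin", "mono_f1_mean", "binoc_f1_mean",
        "percent_diff", "roc_auc", "roc_significant", "direction",
        "relaxed_significant", "relaxed_direction", "n_mono", "n_binoc"])

    # --- population statistics per condition pair and pooled
    summaries = []
    if not mod_df.empty:
        mod_df["outlier"] = False
        for (dom, nd), grp in mod_df.groupby(["dom_bin", "nondom_bin"]):
            vals = grp["percent_diff"].to_numpy()
            if len(vals) >= 3:
                inlier = bs.mad_outlier_filter(vals, k=config.mad_k)
                mod_df.loc[grp.index[~inlier], "outlier"] = True
                vals = vals[inlier]
            key32 = zlib.crc32(f"{dom}|{nd}".encode()) & 0x7FFFFFFF
            summaries.append(bs.population_test(
                vals, condition=f"dom={dom},nd={nd}", n_boot=config.n_boot,
                rng=config.rng_for("bootstrap", key32)))
        pooled = mod_df.loc[~mod_df["outlier"], "percent_diff"].to_numpy()
        summaries.append(bs.population_test(
            pooled, condition="all_pairs", n_boot=config.n_boot,
            rng=config.rng_for("bootstrap", 0)))
        for s, (_, grp) in zip(summaries, mod_df.groupby(["dom_bin", "nondom_bin"])):
            s.n_significant_suppressed = int(
                (grp["roc_significant"] & (grp["direction"] == "suppression")).sum())
            s.n_significant_facilitated = int(
                (grp["roc_significant"] & (grp["direction"] == "facilitation")).sum())

    # --- proportion-of-suppressed trend over dominant contrast (high nd)
    trend = None
    if not mod_df.empty:
        high = mod_df[mod_df["nondom_bin"] == "high"]
        props, cs = [], []
        for dom, grp in high.groupby("dom_bin"):
            if dom == "unbinned":
                continue
            frac = (grp["relaxed_significant"]
                    & (grp["relaxed_direction"] == "suppression")).mean()
            props.append(100.0 * frac)
            cs.append(io_model.bin_by_label(dom).representative)
        if len(props) >= 3:
            order = np.argsort(cs)
            slope, p, df_ = bs.proportion_trend(np.asarray(props)[order],
                                                np.asarray(cs)[order])
            trend = dict(slope=slope, p=p, df=df_,
                         contrasts=list(np.asarray(cs)[order]),
                         percent_suppressed=list(np.asarray(props)[order]))

    # --- class-averaged CRFs
    crf_out = {}
    by_class: dict = {}
    for unit, (cond_f1, _) in unit_condition_f1.items():
        resp = {}
        for key, r in cond_f1.items():
            if len(key) == 3 and key[0] == "achromatic" and key[2] == "zero" \
                    and key[1] != "unbinned":
                resp[io_model.bin_by_label(key[1]).representative] = r.mean
        if len(resp) >= 2:
            by_class.setdefault(unit_classes.get(unit, "?"), {})[unit] = resp
    for klass, units in by_class.items():
        grid, stats_ = bs.crf_average(units)
        crf_out[klass] = dict(contrasts=grid, **stats_)

    manifest = dict(
        n_units_input=len(spikes.units),
        n_low_rate=len(exclusions["low_rate"]),
        n_unstable=len(exclusions["unstable"]),
        n_analyzed=len(retained_units) - len(exclusions["unstable"]),
        n_modulation_records=len(mod_df),
        seed=config.seed,
    )
    assert manifest["n_units_input"] == (manifest["n_analyzed"]
                                         + manifest["n_low_rate"]
                                         + manifest["n_unstable"])
    return AnalysisBundle(
        modulation_records=mod_df,
        population_summaries=summaries,
        stability_report=pd.DataFrame(stab_rows),
        spectral_report=pd.DataFrame(spec_rows),
        classification=pd.DataFrame(class_rows),
        proportion_trend=trend,
        crf=crf_out,
        manifest=manifest,
        errors=errors,
    )


def run_recovery_study(config: PipelineConfig, n_units: int,
                       target_median: float,
                       pairs: list[tuple[float, float]],
                       trials_per_condition: int = 30,
                       rng: np.random.Generator | None = None) -> dict:
    """Median-recovery study: inject a known population median and re-estimate.

    Draws a population whose generative median measured modulation (through
    the noise-free forward map of the measurement chain) equals
    ``target_median`` pooled over the given (dominant, non-dominant)
    contrast pairs, simulates the full factorial design, runs the complete
    analysis, and reports the outlier-filtered sample median of percent
    modulation pooled over the same pairs, with a bootstrap 95% CI.
    """
    from . import synthetic_data as sd

    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = sd.calibrated_population(n_units, target_median, pairs=pairs,
                                          rng=rng)
    doms = sorted({cd for cd, _ in pairs})
    nds = sorted({0.0} | {cnd for _, cnd in pairs})
    design = sd.ExperimentDesign(contrasts_dom=doms, contrasts_nondom=nds,
                                 trials_per_condition=trials_per_condition)
    sim_seed = int(rng.integers(2 ** 31))
    spikes, trials, _ = sd.simulate_experiment(population, design,
                                               seed=sim_seed)
    bundle = run_analysis(config, spikes, trials)
    mod = bundle.modulation_records
    pair_bins = {(io_model.bin_contrast(cd).label, io_model.bin_contrast(cnd).label)
                 for cd, cnd in pairs}
    if mod.empty:
        vals = np.empty(0)
        units = np.empty(0)
    else:
        in_pairs = [(d, n) in pair_bins
                    for d, n in zip(mod["dom_bin"], mod["nondom_bin"])]
        sel = mod[~mod["outlier"].to_numpy() & np.asarray(in_pairs)]
        vals = sel["percent_diff"].to_numpy()
        units = sel["unit_id"].to_numpy()
    median = float(np.median(vals)) if len(vals) else float("nan")
    if len(vals):
        # records from one unit share its monocular samples, so resample
        # whole units (cluster bootstrap), not individual records
        rng_ci = config.rng_for("recovery_ci")
        uniq = np.unique(units)
        groups = [vals[units == u] for u in uniq]
        meds = np.empty(config.n_boot)
        for b in range(config.n_boot):
            pick = rng_ci.integers(0, len(uniq), size=len(uniq))
            meds[b] = np.median(np.concatenate([groups[i] for i in pick]))
        lo, hi = (float(np.quantile(meds, 0.025)),
                  float(np.quantile(meds, 0.975)))
    else:
        lo = hi = float("nan")
    return dict(target_median=target_median, recovered_median=median,
                ci_low=lo, ci_high=hi, n_records=len(vals),
                n_units=n_units, bundle=bundle)


def run_simulation_study(config: PipelineConfig, population, design
                         ) -> dict:
    """Simulate a population, analyze it, and join against ground truth."""
    from . import synthetic_data as sd

    spikes, trials, truth = sd.simulate_experiment(population, design,
                                                   seed=config.seed)
    bundle = run_analysis(config, spikes, trials)
    report = dict(manifest=bundle.manifest, recovery=[], bundle=bundle)
    if bundle.modulation_records.empty:
        return report
    mod = bundle.modulation_records
    for (dom, nd), grp in mod[~mod["outlier"]].groupby(["dom_bin", "nondom_bin"]):
        if dom == "unbinned" or nd == "unbinned":
            continue
        dom_rep = io_model.bin_by_label(dom).representative
        nd_rep = io_model.bin_by_label(nd).representative
        t = truth[(np.isclose(truth["dom_contrast"], dom_rep, atol=0.06))
                  & (np.isclose(truth["nondom_contrast"], nd_rep, atol=0.11))
                  & (truth["chromatic_axis"] == "achromatic")]
        report["recovery"].append(dict(
            dom_bin=dom, nondom_bin=nd, n=len(grp),
            estimated_median=float(grp["percent_diff"].median()),
            true_median_amp=float(t["true_modulation_amp"].median())
            if not t.empty else float("nan"),
        ))
    return report
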