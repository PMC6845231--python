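"""End-to-end parameter-recovery experiments.

Each function here builds synthetic inputs with known ground truth, runs the
full analysis path (simulation -> registration / traces -> QC -> metrics /
stats), and returns the recovered quantities next to their ground-truth
targets.  They double as the package's reproducibility harness: the test
suite asserts their tolerances and ``scripts/acceptance.py`` reports their
numbers.

Problem sizes are chosen to finish in seconds on one CPU while leaving the
statistical checks well powered (600-frame movies, 8 flies x 30 ROIs,
10,000-sample Monte Carlo nulls).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import quad

from . import (
    CellSpec, DrugCondition, MovieConfig, Tuning,
    build_flash_protocol, build_edge_protocol,
    render_movie, simulate_trace_set, register,
    extract_traces, resample_and_segment, compute_dff, trial_average,
    apply_policy, pair_rois, POLICIES, FilterPolicy,
    step_response, plateau_response, integrated_response, edge_amplitude,
    direction_tuning, fly_summary, response_table,
    t_test, holm_adjust, one_way_anova_holm,
    lilliefors_statistic, lilliefors_critical_value,
)
from .simulate import flash_kernel

__all__ = [
    "registration_recovery",
    "flash_metric_recovery",
    "rescue_experiment",
    "filter_fidelity",
    "direction_selectivity",
    "stats_oracles",
    "ddct_checks",
    "edge_geometry",
]


def registration_recovery(seed: int = 0, n_frames: int = 600,
                          size: int = 64, walk_sd: float = 1.0,
                          radius: int = 10,
                          photon_gain: float = 100.0) -> dict:
    """Render a jittered movie and score exact shift recovery vs ground truth."""
    epoch_s = n_frames / 15.0 / 4.0      # 4 epochs at 15 Hz -> n_frames total
    proto = build_flash_protocol(2, epoch_s)
    # aperiodic cell mosaic inside the motion-safe margin (a periodic grid
    # would alias under translation)
    margin = 14
    pitch = (size - 2 * margin) // 2
    jitter = np.random.default_rng(seed + 104729)
    cells = [CellSpec(id=i + 1,
                      center_px=(margin + (i // 3) * pitch
                                 + int(jitter.integers(-4, 5)),
                                 margin + (i % 3) * pitch
                                 + int(jitter.integers(-4, 5))),
                      radius_px=3)
             for i in range(6)]
    cfg = MovieConfig(height_px=size, width_px=size, frame_rate_hz=15.0,
                      photon_gain=photon_gain, motion_walk_sd=walk_sd,
                      motion_walk_max_px=8, seed=seed)
    movie, _, gt = render_movie(cells, proto, cfg)
    _, shifts = register(movie, n_ref_frames=30, search_radius_px=radius)
    accuracy = float((shifts.shifts == gt.shifts).all(axis=1).mean())
    return {"accuracy": accuracy, "n_frames": movie.n_frames,
            "max_true_shift": int(np.abs(gt.shifts).max())}


def flash_metric_recovery(seed: int = 0) -> dict:
    """Noiseless movie -> traces -> metrics; recover the simulated amplitudes.

    The ON cell has amp_transient 1.0, amp_plateau 0.4, tau_rise 0.05 s; the
    analytic integral oracle is adaptive quadrature of the ideal response
    kernel, independent of the 10 Hz pipeline grid.
    """
    cell = CellSpec(id=1, center_px=(24, 24), radius_px=4,
                    amp_transient=1.0, amp_plateau=0.4, tau_rise_s=0.05)
    proto = build_flash_protocol(7, 5.0)
    cfg = MovieConfig(height_px=48, width_px=48, frame_rate_hz=15.0,
                      read_noise_sd=0.0, motion_walk_sd=0.0,
                      shot_noise=False, seed=seed)
    movie, rois, _ = render_movie([cell], proto, cfg)
    ts = extract_traces(movie, rois)
    baseline = cfg.photon_gain * cell.f_baseline
    dff = compute_dff(resample_and_segment(ts, proto),
                      f0_override={1: baseline})
    ta = trial_average(dff)[(1, "flash_on")]
    analytic = 10.0 * quad(lambda t: flash_kernel(np.array([t]), cell)[0],
                           0.0, 5.0, limit=200)[0]
    return {
        "step": step_response(ta), "plateau": plateau_response(ta),
        "integral": integrated_response(ta), "analytic_integral": analytic,
        "true_step": cell.amp_transient, "true_plateau": cell.amp_plateau,
    }


def rescue_experiment(seed: int = 0, n_flies: int = 8,
                      n_rois: int = 30) -> dict:
    """Pharmacogenetic rescue pattern: full block silences ON responses;
    a PTX-insensitive GluClα restores the step, a PTX-insensitive Rdl the
    plateau.

    Cells split the response between a fast glutamatergic transient and a
    slow GABAergic plateau with receptor weights (0.6, 0.4); amplitudes are
    the weights scaled by 1.5.  Pre-drug data decide ROI inclusion (full
    mi1_pharma policy); identical ROIs are carried to the drug conditions.
    """
    w = (0.6, 0.4)
    scale = 1.5
    proto = build_flash_protocol(7, 5.0)
    conditions = {
        "control": DrugCondition("control"),
        "block_both": DrugCondition("block_both", 1.0, 1.0),
        "glu_insensitive": DrugCondition("glu_insensitive", 1.0, 1.0,
                                         insensitive_glu=True),
        "rdl_insensitive": DrugCondition("rdl_insensitive", 1.0, 1.0,
                                         insensitive_gaba=True),
    }
    policy = POLICIES["mi1_pharma"]
    tables: dict[str, list[pd.DataFrame]] = {name: [] for name in conditions}
    rng = np.random.default_rng(seed)
    for f in range(n_flies):
        fly = f"fly{f}"
        cells = [CellSpec(id=i + 1, amp_transient=w[0] * scale,
                          amp_plateau=w[1] * scale, receptor_weights=w)
                 for i in range(n_rois)]
        ts_pre, _ = simulate_trace_set(
            cells, proto, drug=conditions["control"], noise_dff_sd=0.05,
            seed=int(rng.integers(2 ** 31)), split_components=True, fly_id=fly)
        dff_pre = compute_dff(resample_and_segment(ts_pre, proto))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            kept, _ = apply_policy(dff_pre, policy, proto)
        tab = response_table(trial_average(kept), fly_id=fly,
                             condition="control")
        tables["control"].append(tab[tab.kind == "flash_on"])
        for name in ("block_both", "glu_insensitive", "rdl_insensitive"):
            ts_post, _ = simulate_trace_set(
                cells, proto, drug=conditions[name], noise_dff_sd=0.05,
                seed=int(rng.integers(2 ** 31)), split_components=True,
                fly_id=fly)
            dff_post = compute_dff(resample_and_segment(ts_post, proto))
            _, paired_post = pair_rois(kept, dff_post)
            tab = response_table(trial_average(paired_post), fly_id=fly,
                                 condition=name)
            tables[name].append(tab[tab.kind == "flash_on"])
    means = {}
    for name, tabs in tables.items():
        big = pd.concat(tabs, ignore_index=True)
        means[name] = {m: fly_summary(big, m).mean
                       for m in ("step", "plateau")}
    return {
        "control_step": means["control"]["step"],
        "control_plateau": means["control"]["plateau"],
        "blocked_step": means["block_both"]["step"],
        "blocked_plateau": means["block_both"]["plateau"],
        "step_rescue_fraction":
            means["glu_insensitive"]["step"] / means["control"]["step"],
        "plateau_rescue_fraction":
            means["rdl_insensitive"]["plateau"] / means["control"]["plateau"],
        "n_flies": n_flies, "n_rois": n_rois,
    }


def _mixed_population(seed: int, noise: float):
    proto = build_flash_protocol(7, 5.0)
    cells = []
    cid = 1
    for _ in range(20):   # responsive ON cells, peak 1.0
        cells.append(CellSpec(id=cid, polarity=+1,
                              amp_transient=1.0, amp_plateau=0.4))
        cid += 1
    for _ in range(20):   # flat ROIs
        cells.append(CellSpec(id=cid, amp_transient=0.0, amp_plateau=0.0))
        cid += 1
    for _ in range(10):   # anti-correlated (OFF-polarity) ROIs
        cells.append(CellSpec(id=cid, polarity=-1,
                              amp_transient=1.0, amp_plateau=0.4))
        cid += 1
    ts, _ = simulate_trace_set(cells, proto, noise_dff_sd=noise, seed=seed)
    dff = compute_dff(resample_and_segment(ts, proto))
    return proto, dff


def filter_fidelity(seed: int = 0) -> dict:
    """QC policy on 20 responsive + 20 flat + 10 anti-correlated ROIs.

    Noiseless: the mi1_pharma policy keeps exactly the responders.  Noisy:
    survivor counts are non-increasing as each threshold is tightened.
    """
    proto, dff = _mixed_population(seed, noise=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        kept, report = apply_policy(dff, POLICIES["mi1_pharma"], proto)
        proto_n, dff_n = _mixed_population(seed + 1, noise=0.08)
        abs_counts = [apply_policy(dff_n, FilterPolicy(True, None, thr),
                                   proto_n)[1].n_after
                      for thr in (0.0, 0.25, 0.5, 1.0)]
        sd_counts = [apply_policy(dff_n, FilterPolicy(True, thr, None),
                                  proto_n)[1].n_after
                     for thr in (1.0, 0.2, 0.05, 0.0)]
    monotone = (abs_counts == sorted(abs_counts, reverse=True)
                and sd_counts == sorted(sd_counts, reverse=True))
    return {"n_survivors": report.n_after,
            "survivor_ids_are_responders":
                sorted(kept.roi_ids) == list(range(1, 21)),
            "thresholds_monotone": bool(monotone),
            "n_population": report.n_before}


def direction_selectivity(seed: int = 0, n_isotropic: int = 50) -> dict:
    """Direction tuning recovery on moving-edge responses.

    Cosine-tuned cells with on-grid preferred directions give DSI = 1 with
    zero PD error (the null direction is rectified to zero); isotropic cells
    at the simulated noise level stay near DSI 0; the DSI is invariant to
    scaling all direction responses.
    """
    proto = build_edge_protocol(20.0, 3, 2.0, seed=seed)

    def edge_amps(cell, noise, cell_seed):
        ts, _ = simulate_trace_set([cell], proto, noise_dff_sd=noise,
                                   seed=cell_seed)
        dff = compute_dff(resample_and_segment(ts, proto), "gray_last_second")
        avgs = trial_average(dff)
        return {k[3]: edge_amplitude(v) for k, v in avgs.items()
                if k[1] == "edge" and k[2] > 0}

    pd_errors, tuned_dsis = [], []
    for i, pref in enumerate(np.arange(0.0, 360.0, 45.0)):
        cell = CellSpec(id=1, tuning=Tuning("cosine_rectified", float(pref)))
        dt = direction_tuning(edge_amps(cell, 0.0, 0))
        tuned_dsis.append(dt.dsi)
        pd_errors.append(abs((dt.pd_deg - pref + 180.0) % 360.0 - 180.0))
    iso_dsis = []
    for i in range(n_isotropic):
        dt = direction_tuning(edge_amps(CellSpec(id=1), 0.05, seed * 7919 + i))
        iso_dsis.append(dt.dsi)
    amps = edge_amps(CellSpec(id=1), 0.05, seed + 1)
    a = direction_tuning(amps)
    b = direction_tuning({d: 3.7 * v for d, v in amps.items()})
    return {
        "tuned_dsi_min": float(np.min(tuned_dsis)),
        "tuned_pd_error_max_deg": float(np.max(pd_errors)),
        "isotropic_mean_dsi": float(np.mean(iso_dsis)),
        "dsi_scale_invariance_error": abs(a.dsi - b.dsi),
        "n_isotropic": n_isotropic,
    }


def stats_oracles(seed: int = 0, n_mc_lilliefors: int = 10_000,
                  n_null_chain: int = 2_000) -> dict:
    """Closed-form statistics oracles plus Monte-Carlo calibrations.

    F and t statistics on hand-built examples; Holm on a known triple;
    Lilliefors null rejection rate at n = 50; type-I error of the full
    ANOVA -> Holm-pairwise chain on null three-group data (n = 10 each).
    """
    omnibus, _ = one_way_anova_holm([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    paired = t_test([1.5, 2.5, 3.0], [1.0, 2.0, 3.0], paired=True)
    holm = holm_adjust([0.01, 0.04, 0.03])

    rng = np.random.default_rng(seed)
    crit = lilliefors_critical_value(50, 0.05, n_mc=20_000,
                                     seed=int(rng.integers(2 ** 31)))
    samples = rng.standard_normal((n_mc_lilliefors, 50))
    d = np.array([lilliefors_statistic(s) for s in samples])
    lf_rate = float((d > crit).mean())

    false_pos = 0
    for _ in range(n_null_chain):
        groups = rng.standard_normal((3, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omni, pairwise = one_way_anova_holm(list(groups))
        if omni.p < 0.05 and min(r.p_adjusted for r in pairwise) < 0.05:
            false_pos += 1
    chain_rate = false_pos / n_null_chain
    return {
        "anova_f": omnibus.statistic, "anova_df": omnibus.df,
        "paired_t": paired.statistic,
        "holm_adjusted": [float(x) for x in holm],
        "lilliefors_null_rejection_rate": lf_rate,
        "chain_type_i_error": chain_rate,
        "n_mc_lilliefors": n_mc_lilliefors, "n_null_chain": n_null_chain,
    }


def ddct_checks(seed: int = 0) -> dict:
    """ΔΔCt worked example, shift invariance, and fold-change recovery."""
    from . import qpcr

    rows = []
    for cond, ct_t, ct_r in (("ND", 20.0, 18.0), ("D", 22.0, 18.0)):
        for gene, ct in (("target", ct_t), ("reference", ct_r)):
            for tech in range(3):
                rows.append({"condition": cond, "gene": gene, "bio_rep": 1,
                             "tech_rep": tech, "ct": ct})
    means = qpcr.mean_ct(pd.DataFrame(rows))
    worked = qpcr.ddct_percent(means).mean

    rng = np.random.default_rng(seed)
    shift_err = 0.0
    for _ in range(20):
        shifted = means.assign(ct=means.ct + rng.uniform(-4, 4))
        shift_err = max(shift_err,
                        abs(qpcr.ddct_percent(shifted).mean - worked))

    # simulated 2-fold dilution series: Ct rises by exactly 1 per dilution
    log10_template = np.array([0.0, -np.log10(2), -2 * np.log10(2),
                               -3 * np.log10(2)])
    ct = 20.0 - log10_template / np.log10(2.0)
    eff = qpcr.standard_curve_efficiency(log10_template, ct)
    # a true 2-fold knockdown (one extra target cycle) at E = 2
    means_2x = means.copy()
    sel = (means_2x.condition == "D") & (means_2x.gene == "target")
    means_2x.loc[sel, "ct"] = 21.0
    fold = qpcr.ddct_percent(means_2x).mean
    return {
        "worked_example_percent": worked,
        "max_shift_invariance_error": shift_err,
        "dilution_efficiency": eff,
        "twofold_knockdown_percent": fold,
    }


def edge_geometry(seed: int = 0) -> dict:
    """Edge-protocol geometry: epoch length and retinotopic peak timing.

    Two ROIs whose receptive-field centers sit 60° apart along the motion
    axis see the edge front 3.0 s apart at 20°/s.
    """
    proto = build_edge_protocol(20.0, 3, 2.0, seed=seed)
    edge_s = next(e.duration_s for e in proto.epochs if e.kind == "edge")
    near = CellSpec(id=1, rf_center_deg=(-30.0, 0.0))
    far = CellSpec(id=2, rf_center_deg=(30.0, 0.0))
    ts, _ = simulate_trace_set([near, far], proto, frame_rate_hz=15.0,
                               noise_dff_sd=0.0, seed=seed)
    onsets = proto.onsets()
    separations = []
    for e, onset in zip(proto.epochs, onsets):
        if e.kind == "edge" and e.contrast > 0 and e.direction_deg == 0.0:
            sel = (ts.times >= onset) & (ts.times <= onset + e.duration_s + 1.5)
            tt = ts.times[sel]
            p1 = tt[np.argmax(ts.values[0][sel])]
            p2 = tt[np.argmax(ts.values[1][sel])]
            separations.append(p2 - p1)
    return {"edge_epoch_s": float(edge_s),
            "peak_separation_s": float(np.mean(separations)),
            "n_epochs_checked": len(separations)}
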