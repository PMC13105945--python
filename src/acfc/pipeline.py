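"""End-to-end orchestration of the ACFC stages for one participant or cohort.

These helpers wire the stage modules together in the order the method
prescribes: preprocessing, band-power extraction, rate extraction,
global coupling matrices and networks, windowed coupling time series,
and variability statistics.  The CLI is a thin wrapper over them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .bandpower import band_power_series, make_band_scheme, zscore_global
from .config import PipelineConfig, get_logger
from .coupling import CouplingMatrix, build_network, coupling_matrix, mean_link_strength
from .dynamic import histogram_profile, windowed_coupling_all
from .preprocess import preprocess_recording
from .rates import br_tfr, correct_artifacts, detect_r_peaks, hr_series
from .recording import ChannelKind, Recording, SegmentLabel
from .variability import dfa, magnitude_sign, static_stats

__all__ = [
    "split_channels",
    "emg_band_power",
    "heart_rate",
    "breathing_rate",
    "analyze_global",
    "analyze_dynamic",
    "variability_table",
    "run_participant",
]

log = get_logger(__name__)


def split_channels(recs: list[Recording]):
    """Split a participant's recordings into (emg dict, ekg, resp)."""
    emg = {r.channel_id: r for r in recs if r.kind == ChannelKind.EMG}
    ekg = next((r for r in recs if r.kind == ChannelKind.EKG), None)
    resp = next((r for r in recs if r.kind == ChannelKind.RESP), None)
    return emg, ekg, resp


def _crop(rec: Recording, segment: SegmentLabel | None) -> Recording:
    return rec if segment is None else rec.crop(segment.start, segment.end)


def emg_band_power(
    emg: dict[str, Recording],
    config: PipelineConfig,
    window: float | None = None,
    step: float | None = None,
    segment: SegmentLabel | None = None,
    preprocess: bool = True,
) -> dict[str, list]:
    """Globally z-scored band-power series per EMG channel."""
    window = config.bp_window if window is None else window
    step = config.bp_step if step is None else step
    scheme = make_band_scheme(config.band_low, config.band_width, config.band_count,
                              config.bin_width, config.exclusions)
    out = {}
    for name, rec in emg.items():
        rec = _crop(rec, segment)
        if preprocess:
            rec = preprocess_recording(rec, config.emg_band, config.ekg_band,
                                       config.notch_center, config.notch_width,
                                       config.filter_order)
        series = band_power_series(rec, scheme, window=window, step=step,
                                   taper=config.taper)
        out[name] = [zscore_global(s) for s in series]
    return out


def heart_rate(ekg: Recording, config: PipelineConfig,
               segment: SegmentLabel | None = None, preprocess: bool = True):
    """Artifact-corrected instantaneous HR series from an EKG channel."""
    rec = _crop(ekg, segment)
    if preprocess:
        rec = preprocess_recording(rec, config.emg_band, config.ekg_band,
                                   config.notch_center, config.notch_width,
                                   config.filter_order)
    peaks = detect_r_peaks(rec)
    hr = hr_series(peaks, step=config.hr_step)
    return correct_artifacts(hr, window=config.hr_artifact_window, k=config.hr_artifact_k)


def breathing_rate(resp: Recording, config: PipelineConfig,
                   segment: SegmentLabel | None = None):
    """Instantaneous BR series from the respiratory belt (spectral ridge)."""
    rec = _crop(resp, segment)
    return br_tfr(rec, window=config.br_window, step=config.br_step,
                  smooth=config.br_smooth, fmin=config.br_fmin, fmax=config.br_fmax)


def analyze_global(recs: list[Recording], config: PipelineConfig,
                   segment: SegmentLabel | None = None) -> dict:
    """Phase-1 global coupling matrices for every system pair.

    Returns ``{"intermuscular": {pair: matrix}, "cardio": {...},
    "resp": {...}}``; cardio/resp entries are present only when the
    corresponding channel exists.
    """
    emg, ekg, resp = split_channels(recs)
    bp = emg_band_power(emg, config, segment=segment)
    names = sorted(bp)
    result: dict = {"intermuscular": {}}
    for a, b in itertools.combinations(names, 2):
        result["intermuscular"][(a, b)] = coupling_matrix(bp[a], bp[b], lag=config.lag)
    if ekg is not None:
        hr = heart_rate(ekg, config, segment=segment)
        result["cardio"] = {("Heart", m): coupling_matrix(hr, bp[m], lag=config.lag)
                            for m in names}
    if resp is not None:
        br = breathing_rate(resp, config, segment=segment)
        bp_slow = emg_band_power(emg, config, window=config.resp_bp_window,
                                 step=config.resp_bp_step, segment=segment)
        result["resp"] = {("Respiration", m): coupling_matrix(br, bp_slow[m],
                                                              lag=config.lag)
                          for m in names}
    return result


def analyze_dynamic(recs: list[Recording], config: PipelineConfig,
                    segment: SegmentLabel | None = None) -> dict:
    """Phase-2 windowed coupling time series for every link."""
    emg, ekg, resp = split_channels(recs)
    bp = emg_band_power(emg, config, segment=segment)
    names = sorted(bp)
    result: dict = {"intermuscular": []}
    for a, b in itertools.combinations(names, 2):
        result["intermuscular"].extend(windowed_coupling_all(
            bp[a], bp[b], window=config.dyn_window, step=config.dyn_step, lag=config.lag))
    if ekg is not None:
        hr = heart_rate(ekg, config, segment=segment)
        result["cardio"] = []
        for m in names:
            result["cardio"].extend(windowed_coupling_all(
                hr, bp[m], window=config.dyn_window, step=config.dyn_step, lag=config.lag))
    if resp is not None:
        br = breathing_rate(resp, config, segment=segment)
        bp_slow = emg_band_power(emg, config, window=config.resp_bp_window,
                                 step=config.resp_bp_step, segment=segment)
        result["resp"] = []
        for m in names:
            result["resp"].extend(windowed_coupling_all(
                br, bp_slow[m], window=config.dyn_window, step=config.dyn_step,
                lag=config.lag))
    return result


def variability_table(cts_list, config: PipelineConfig | None = None,
                      with_dfa: bool = True) -> pd.DataFrame:
    """Tidy per-link variability statistics (moments, DFA alpha, sign alpha)."""
    config = config or PipelineConfig()
    rows = []
    for cts in cts_list:
        vals = cts.valid_values()
        row = {
            "pair": "-".join(cts.pair_id), "link": "-".join(cts.link_id),
            "n_windows": int(vals.size),
        }
        try:
            st = static_stats(cts)
            row.update(sd=st.sd, kurtosis=st.kurtosis,
                       excess_kurtosis=st.excess_kurtosis, skewness=st.skewness)
        except ValueError:
            row.update(sd=np.nan, kurtosis=np.nan, excess_kurtosis=np.nan,
                       skewness=np.nan)
        alpha = np.nan
        if with_dfa and vals.size >= 64:
            try:
                alpha = dfa(vals, detrend_order=config.dfa_order).alpha
            except ValueError:
                pass
        row["dfa_alpha"] = alpha
        if vals.size >= 2:
            ms = magnitude_sign(cts)
            row["mean_abs_increment"] = float(ms.magnitude.mean()) if ms.increments.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_participant(recs: list[Recording], config: PipelineConfig | None = None,
                    segment: SegmentLabel | None = None) -> dict:
    """Full single-participant analysis bundle, ready for ``io.write_outputs``."""
    config = config or PipelineConfig()
    config.log_resolved("run_participant")
    bundle: dict = {}
    glob = analyze_global(recs, config, segment=segment)
    all_mats: list[CouplingMatrix] = []
    summary_rows = []
    for system, mats in glob.items():
        for pair, mat in mats.items():
            key = f"global_{system}_{'-'.join(pair)}"
            bundle[key] = mat
            all_mats.append(mat)
            summary_rows.append({"system": system, "pair": "-".join(pair),
                                 "mean_link_strength": mean_link_strength(mat)})
    bundle["global_summary"] = pd.DataFrame(summary_rows)
    bundle["network"] = build_network(all_mats, thresholds=config.link_classes)

    dyn = analyze_dynamic(recs, config, segment=segment)
    long_rows = []
    hist_rows = []
    all_cts = []
    for system, series_list in dyn.items():
        all_cts.extend(series_list)
        for cts in series_list:
            pair, link = "-".join(cts.pair_id), "-".join(cts.link_id)
            for t, v in zip(cts.times, cts.values):
                long_rows.append({"system": system, "pair": pair, "link": link,
                                  "t": t, "r": v})
            prof = histogram_profile(cts, dc=config.hist_dc)
            centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
            for c, cnt, resc in zip(centers, prof.counts, prof.rescaled):
                hist_rows.append({"system": system, "pair": pair, "link": link,
                                  "bin_center": c, "count": int(cnt),
                                  "rescaled": resc})
    bundle["coupling_timeseries"] = pd.DataFrame(long_rows)
    bundle["coupling_histograms"] = pd.DataFrame(hist_rows)
    bundle["variability"] = variability_table(all_cts, config)
    return bundle
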