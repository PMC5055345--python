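"""End-to-end analyses over a cohort: periodicity/chromatin concordance,
DI-vs-periodicity binning, and variant effects.

Each run writes tab-separated tables plus a JSON manifest (config, seed,
package version) sufficient to reproduce the outputs byte-identically.
Plots are deliberately not produced here; the TSVs are the contract.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .genome_io import (
    N1_WINDOW,
    NFR_WINDOW,
    RelativeWindow,
    SCAN_WINDOW,
    TAG_WINDOW,
    TARGET_FREQUENCY,
)
from .initiation import (
    cosine_covariance_rank,
    cumulative_micropeak_frequency,
    mean_dispersion_index,
    micro_peaks,
    positions_from_counts,
)
from .nucleosomes import aggregate_profile
from .periodicity import (
    DINUCLEOTIDE_CODES,
    concordance_call,
    dinucleotide_track,
    periodicity_profile,
)
from .synthetic import Cohort, SimConfig, simulate_cohort
from .variant_effects import (
    delta_di_by_window,
    delta_power_vs_delta_di,
    window_power,
)

log = logging.getLogger("nucperiod")

_FLOAT_FMT = "%.10g"
NUC_SPAN = RelativeWindow(-1000, 1001)
# aligned so the sliding grid contains the canonical N+1 window [+50,+200)
EFFECT_SPAN = RelativeWindow(-1070, SCAN_WINDOW.end)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _manifest(outdir: Path, name: str, cfg: SimConfig, params: dict) -> None:
    payload = dict(
        analysis=name,
        package_version=__version__,
        seed=cfg.seed,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg).items()},
        params=params,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _promoter_profiles(cohort: Cohort, code: str):
    """Per-promoter periodicity profile of one dinucleotide code."""
    out = {}
    for pid in cohort.promoters.ids():
        seq = cohort.members[pid].oriented_seq
        track = dinucleotide_track(seq, code)
        out[pid] = periodicity_profile(track, start_offset=SCAN_WINDOW.start)
    return out


def run_fig1(cohort: Cohort, outdir, code: str = "WW", block: int = 10) -> dict:
    """Periodicity/nucleosome concordance analysis.

    Orders promoters by the Pearson correlation between their periodicity
    profile and their own smoothed nucleosome profile over +-1 kb, writes
    the block-averaged heatmap matrix (rows of `block` promoters), the
    per-code concordance table, and aggregate nucleosome profiles stratified
    by the number of concordant dinucleotide codes (0..4).
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tags = cohort.mnase_tags()

    profiles = {c: _promoter_profiles(cohort, c) for c in DINUCLEOTIDE_CODES}
    centers = next(iter(profiles[code].values())).window_centers

    # per-promoter nucleosome profile sampled at the profile centers
    correlations = {}
    n_missing = 0
    heat_rows = {}
    for p in cohort.promoters:
        single = cohort.promoters.subset([p.id])
        offs, smoothed, _ = aggregate_profile(tags, single, NUC_SPAN)
        sel = (centers >= NUC_SPAN.start) & (centers < NUC_SPAN.end)
        nuc_at_centers = smoothed[centers[sel] - NUC_SPAN.start]
        powers = profiles[code][p.id].powers[sel]
        if nuc_at_centers.std() == 0 or powers.std() == 0:
            n_missing += 1
            continue
        correlations[p.id] = float(stats.pearsonr(powers, nuc_at_centers)[0])
        heat_rows[p.id] = profiles[code][p.id].powers
    if n_missing:
        log.info("fig1: %d promoter(s) lacked usable nucleosome data", n_missing)

    order = sorted(correlations, key=lambda pid: (-correlations[pid], pid))
    _write(pd.DataFrame(dict(id=order,
                             correlation=[correlations[i] for i in order])),
           outdir / "fig1_order.tsv")

    # heatmap: block-average of `block` promoters per row, ordered
    rows = []
    for b in range(0, len(order), block):
        ids = order[b:b + block]
        rows.append(np.mean([heat_rows[i] for i in ids], axis=0))
    heat = pd.DataFrame(rows, columns=[str(c) for c in centers])
    heat.insert(0, "row", range(len(rows)))
    _write(heat, outdir / "fig1_heatmap.tsv")

    # concordance per code and strata
    conc_rows = []
    for p in cohort.promoters:
        flags = {c: concordance_call(profiles[c][p.id], NFR_WINDOW, N1_WINDOW)
                 for c in DINUCLEOTIDE_CODES}
        conc_rows.append(dict(id=p.id,
                              **{c: int(v) for c, v in flags.items()},
                              n_concordant=sum(flags.values())))
    conc = pd.DataFrame(conc_rows)
    _write(conc, outdir / "fig1_concordance.tsv")

    strata_frames = []
    for k in range(len(DINUCLEOTIDE_CODES) + 1):
        ids = conc.loc[conc["n_concordant"] == k, "id"].tolist()
        if not ids:
            continue
        offs, smoothed, _ = aggregate_profile(tags, cohort.promoters.subset(ids),
                                              NUC_SPAN)
        strata_frames.append(pd.DataFrame(
            dict(stratum=k, offset=offs, occupancy=smoothed, n_promoters=len(ids))))
    _write(pd.concat(strata_frames, ignore_index=True),
           outdir / "fig1_strata_profiles.tsv")

    _manifest(outdir, "fig1", cohort.cfg, dict(code=code, block=block))
    log.info("fig1 done in %.1fs", time.monotonic() - t0)
    return dict(order=order, correlations=correlations, concordance=conc)


def _mean_n1_power(seq: str) -> float:
    """Mean power of the 4 dinucleotide codes over the N+1 window."""
    lo = N1_WINDOW.start - SCAN_WINDOW.start
    window = seq[lo:lo + len(N1_WINDOW)]
    return float(np.mean([window_power(window, c) for c in DINUCLEOTIDE_CODES]))


def run_fig3(cohort: Cohort, outdir, bin_size: int = 20,
             micropeak_min_tags: Optional[int] = None) -> dict:
    """DI binning/regression and micro-peak aggregates per promoter class."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .promoter_classes import bin_by_di

    if micropeak_min_tags is None:
        # depth-scaled threshold: the canonical 100-tag cutoff assumes
        # genome-scale libraries; scale by expected tags per promoter
        micropeak_min_tags = max(5, int(cohort.cfg.tag_depth * 0.1))

    rows = []
    marks: Dict[str, np.ndarray] = {}
    for p in cohort.promoters:
        m = cohort.members[p.id]
        di = mean_dispersion_index(
            positions_from_counts(c) for c in m.cage_ref)
        merged = np.sum(m.cage_ref, axis=0)
        marks[p.id] = micro_peaks(merged, min_tags=micropeak_min_tags)
        rows.append(dict(id=p.id, di=di.di, n_tags=di.n_tags,
                         power=_mean_n1_power(m.oriented_seq),
                         cpe="TATA+" in p.labels))
    table = pd.DataFrame(rows)
    _write(table, outdir / "fig3_promoters.tsv")

    bins = bin_by_di(table, bin_size=bin_size)
    _write(bins.table, outdir / "fig3_bins.tsv")
    if bins.regression is not None:
        reg = bins.regression
        _write(pd.DataFrame([dict(slope=reg.slope, intercept=reg.intercept,
                                  r2=reg.r2, pvalue=reg.pvalue)]),
               outdir / "fig3_regression.tsv")

    # micro-peak aggregates per class (TATA x focused/broad by median DI)
    finite = table[np.isfinite(table["di"])]
    median_di = float(finite.loc[~finite["cpe"], "di"].median())
    agg_frames = []
    for name, ids in _fig3_classes(table, median_di).items():
        if not ids:
            continue
        offs, freq = cumulative_micropeak_frequency([marks[i] for i in ids])
        agg_frames.append(pd.DataFrame(
            dict(promoter_class=name, offset=offs, frequency=freq,
                 n_promoters=len(ids))))
    _write(pd.concat(agg_frames, ignore_index=True),
           outdir / "fig3_micropeaks.tsv")

    ranked = cosine_covariance_rank(marks)
    _write(pd.DataFrame(ranked, columns=["id", "covariance"]),
           outdir / "fig3_cosine_rank.tsv")

    _manifest(outdir, "fig3", cohort.cfg,
              dict(bin_size=bin_size, micropeak_min_tags=micropeak_min_tags,
                   median_di=median_di))
    log.info("fig3 done in %.1fs", time.monotonic() - t0)
    return dict(table=table, bins=bins, marks=marks, ranked=ranked)


def _fig3_classes(table: pd.DataFrame, median_di: float) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    cpe = table["cpe"].astype(bool)
    finite = np.isfinite(table["di"])
    out["TATA"] = table.loc[cpe, "id"].tolist()
    out["TATA-less_focused"] = table.loc[
        ~cpe & finite & (table["di"] <= median_di), "id"].tolist()
    out["TATA-less_broad"] = table.loc[
        ~cpe & finite & (table["di"] > median_di), "id"].tolist()
    return out


def run_fig4(cohort: Cohort, outdir) -> dict:
    """Per-window variant effects on DI and the Delta-power regression."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    delta_di: Dict[str, float] = {}
    variant_offsets = {}
    ref_seqs = {}
    patched = {}
    for p in cohort.promoters:
        m = cohort.members[p.id]
        if not m.cage_sample:
            continue
        di_ref = mean_dispersion_index(
            positions_from_counts(c) for c in m.cage_ref)
        di_alt = mean_dispersion_index(
            positions_from_counts(c) for c in m.cage_sample)
        if not (di_ref.defined and di_alt.defined):
            continue
        delta_di[p.id] = di_alt.di - di_ref.di
        variant_offsets[p.id] = [(v.pos, v.kind) for v in m.variants]
        if m.patched is not None:
            ref_seqs[p.id] = m.oriented_seq
            patched[p.id] = m.patched

    for kind in ("SNP", "indel"):
        df = delta_di_by_window(delta_di, variant_offsets, kind=kind,
                                span=EFFECT_SPAN)
        _write(df, outdir / f"fig4_delta_di_{kind}.tsv")

    slopes = delta_power_vs_delta_di(
        ref_seqs, patched, delta_di, variant_offsets,
        seq_start_offset=SCAN_WINDOW.start, span=EFFECT_SPAN)
    _write(slopes, outdir / "fig4_slopes.tsv")

    _manifest(outdir, "fig4", cohort.cfg, dict())
    log.info("fig4 done in %.1fs", time.monotonic() - t0)
    return dict(delta_di=delta_di, slopes=slopes)


# ---------------------------------------------------------------------------
# synthetic end-to-end entry points


def run_synthetic_fig1(cfg: SimConfig, outdir) -> dict:
    return run_fig1(simulate_cohort(cfg), outdir)


def run_synthetic_fig3(cfg: SimConfig, outdir, bin_size: int = 20) -> dict:
    return run_fig3(simulate_cohort(cfg), outdir, bin_size=bin_size)


def run_synthetic_fig4(cfg: SimConfig, outdir) -> dict:
    return run_fig4(simulate_cohort(cfg), outdir)
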