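"""End-to-end synthetic study: simulate → call → classify → compare → enrich.

``run_study`` executes the whole analysis on a planted genome and writes
every intermediate plus a flat, deterministic report.  One seed governs
the run; repeated runs with the same config produce byte-identical
reports (wall-clock timings go to ``run.log`` only, which is the single
non-deterministic output).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import boundaries as bdyn
from . import enrichment as enr
from . import peaks as pk
from . import simulate as sim
from . import tads as tc
from .genome import GenomeLayout, GenomicInterval, IntervalSet, write_bed

__all__ = ["StudyConfig", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Simulation conditions plus every analysis-stage parameter."""

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    # TAD calling
    window_bins: int = 50
    min_tad_bins: int = 3
    boundary_flank: int = 100_000
    balance: bool = True
    hmm_max_iter: int = 200
    # enrichment
    n_shuffles: int = 200
    shuffle_max_tries: int = 10_000
    profile_flank: int = 500_000
    profile_bin: int = 20_000
    hk_window: int = 100_000
    write_matrices: bool = False

    @property
    def seed(self) -> int:
        return self.sim.seed

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, sim=replace(self.sim, seed=seed))


def _fmt(v: object) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _call_condition(
    matrix_by_chrom: dict[str, "sim.ContactMatrix"],
    config: StudyConfig,
    layout: GenomeLayout,
    hmm_seed: int,
) -> tuple[IntervalSet, IntervalSet, dict, dict[str, tc.DirectionalityTrack]]:
    """Balance, DI, HMM, decode and infer TADs for one condition."""
    tracks: dict[str, tc.DirectionalityTrack] = {}
    for chrom, m in matrix_by_chrom.items():
        if config.balance:
            _, m = tc.ice_balance(m)
        tracks[chrom] = tc.directionality_index(m, window_bins=config.window_bins)
    # one HMM over all chromosomes: concatenate tracks for the fit
    all_di = np.concatenate([t.DI for t in tracks.values()])
    pooled = tc.DirectionalityTrack(
        chrom="*", bin_size=layout.bin_size or 1, DI=all_di,
        A=np.zeros_like(all_di), B=np.zeros_like(all_di),
        window_bins=config.window_bins,
        mask=~np.isfinite(all_di),
    )
    params = tc.fit_hmm(pooled, max_iter=config.hmm_max_iter, seed=hmm_seed)
    tad_list: list[GenomicInterval] = []
    for chrom in layout.names:
        if chrom not in tracks:
            continue
        path = tc.decode_states(tracks[chrom], params)
        called = tc.infer_tads(
            path,
            min_tad_bins=config.min_tad_bins,
            chrom_length=layout.length(chrom),
        )
        tad_list.extend(called)
    tads = IntervalSet(tad_list, layout=layout, is_sorted=True)
    bounds, _ = tc.call_boundaries(tads, layout, flank=config.boundary_flank)
    hmm_info = {
        "means": params.means.tolist(),
        "variances": params.variances.tolist(),
    }
    return tads, bounds, hmm_info, tracks


def run_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Run the full planted-truth study and return the flat report dict."""
    t0 = time.monotonic()
    out = Path(outdir)
    for sub in ("truth", "called", "peaks", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.monotonic() - t0:8.2f}s] {stage}: {msg}")

    scfg = config.sim
    layout = scfg.layout
    report: dict[str, object] = {"seed": scfg.seed}
    for key, val in asdict(scfg).items():
        if key == "layout":
            report["layout"] = ";".join(f"{c}:{l}" for c, l in layout.chromosomes)
            report["bin_size"] = layout.bin_size
        else:
            report[f"sim.{key}"] = val
    for key in (
        "window_bins", "min_tad_bins", "boundary_flank", "balance",
        "n_shuffles", "profile_flank", "profile_bin", "hk_window",
    ):
        report[f"stage.{key}"] = getattr(config, key)

    # -- stage 1: planted truth -------------------------------------------
    control_tads, gaps = sim.simulate_tad_segmentation(scfg)
    btable = sim.internal_boundaries(control_tads, layout)
    btable, assignment = sim.assign_persistent_sites(btable, scfg, scfg.rng(11))
    kd_tads, merge_events, btable = sim.derive_knockdown_truth(
        control_tads, btable, scfg, scfg.rng(12)
    )
    log("truth", f"{len(control_tads)} control TADs, {len(merge_events)} planted merges")

    collection, peak_truth = sim.simulate_peak_collection(
        btable, assignment, scfg, scfg.rng(13)
    )
    panel_bounds, panel_peaks, presence = sim.simulate_celltype_panel(
        btable, peak_truth, scfg, scfg.rng(14)
    )
    core_centers = IntervalSet(
        [
            GenomicInterval(
                r.chrom,
                max(0, r.pos - scfg.boundary_flank),
                min(layout.length(r.chrom), r.pos + scfg.boundary_flank),
            )
            for r in presence[presence["is_core"]].itertuples()
        ],
        layout=layout,
    ).merged()
    genes, hk_flags = sim.simulate_gene_annotation(core_centers, scfg, scfg.rng(15))

    write_bed(control_tads, out / "truth" / "control_tads.bed")
    write_bed(kd_tads, out / "truth" / "knockdown_tads.bed")
    btable.to_csv(out / "truth" / "boundaries.tsv", sep="\t", index=False)
    peak_truth.to_csv(out / "truth" / "peaks.tsv", sep="\t", index=False)
    presence.to_csv(out / "truth" / "panel_presence.tsv", sep="\t", index=False)
    write_bed(genes, out / "truth" / "genes.bed")
    with open(out / "truth" / "merge_events.tsv", "w") as fh:
        fh.write("absorbing\tabsorbed\tdissolved\n")
        for ev in merge_events:
            fh.write(
                f"{ev.absorbing.chrom}:{ev.absorbing.start}-{ev.absorbing.end}\t"
                + ",".join(f"{t.start}-{t.end}" for t in ev.absorbed)
                + "\t"
                + ",".join(map(str, ev.dissolved))
                + "\n"
            )

    # -- stage 2: matrices and TAD calling --------------------------------
    called: dict[str, tuple[IntervalSet, IntervalSet]] = {}
    for cond, tads, stream in (
        ("control", control_tads, 21),
        ("knockdown", kd_tads, 22),
    ):
        rng = scfg.rng(stream)
        mats = {
            chrom: sim.simulate_contact_matrix(tads, scfg, chrom, rng)
            for chrom in layout.names
        }
        if config.write_matrices:
            from .genome import write_contact_matrix

            write_contact_matrix(
                mats, layout, out / "called" / f"{cond}_bins.bed",
                out / "called" / f"{cond}_counts.tsv",
            )
        c_tads, c_bounds, hmm_info, tracks = _call_condition(
            mats, config, layout, hmm_seed=scfg.seed
        )
        called[cond] = (c_tads, c_bounds)
        write_bed(c_tads, out / "called" / f"{cond}_tads.bed")
        write_bed(c_bounds, out / "called" / f"{cond}_boundaries.bed")
        with open(out / "called" / f"{cond}_hmm.txt", "w") as fh:
            for k, v in hmm_info.items():
                fh.write(f"{k}=" + ",".join(format(x, ".6g") for x in v) + "\n")
        with open(out / "called" / f"{cond}_di.bedgraph", "w") as fh:
            bs = layout.bin_size or 1
            for chrom, track in tracks.items():
                clen = layout.length(chrom)
                for b, di in enumerate(track.DI):
                    if np.isfinite(di):
                        fh.write(
                            f"{chrom}\t{b * bs}\t{min((b + 1) * bs, clen)}\t"
                            f"{format(di, '.6g')}\n"
                        )
        summ = tc.tad_summary(c_tads)
        truth_summ = tc.tad_summary(tads)
        for k, v in summ.items():
            report[f"tads.{cond}.called.{k}"] = v
        for k, v in truth_summ.items():
            report[f"tads.{cond}.planted.{k}"] = v
        log("call", f"{cond}: {summ['count']} TADs called ({truth_summ['count']} planted)")

    # planted-boundary recovery (control condition)
    planted_pos: dict[str, np.ndarray] = {
        chrom: grp["pos"].to_numpy()
        for chrom, grp in btable.groupby("chrom")
    }
    rec = tc.boundary_recovery(planted_pos, called["control"][0], layout)
    for k, v in rec.items():
        report[f"recovery.control.{k}"] = v

    # -- stage 3: boundary dynamics ---------------------------------------
    comp = bdyn.compare_boundaries(called["control"][1], called["knockdown"][1])
    for k, v in comp.counts.items():
        report[f"boundaries.called.{k}"] = v
    n_a = len(called["control"][1])
    report["boundaries.called.total_control"] = n_a
    report["boundaries.called.maintained_fraction"] = (
        comp.counts["maintained"] / n_a if n_a else float("nan")
    )

    detected = bdyn.detect_merged_tads(
        control_tads, kd_tads, boundary_flank=config.boundary_flank
    )
    truth_keys = {(ev.absorbing.chrom, ev.absorbing.start, ev.absorbing.end,
                   tuple((t.start, t.end) for t in ev.absorbed)) for ev in merge_events}
    det_keys = {(ev.absorbing.chrom, ev.absorbing.start, ev.absorbing.end,
                 tuple((t.start, t.end) for t in ev.absorbed)) for ev in detected}
    tp = len(truth_keys & det_keys)
    report["merges.truth_count"] = len(truth_keys)
    report["merges.detected_count"] = len(det_keys)
    report["merges.precision"] = tp / len(det_keys) if det_keys else float("nan")
    report["merges.recall"] = tp / len(truth_keys) if truth_keys else float("nan")
    called_merges = bdyn.detect_merged_tads(
        called["control"][0], called["knockdown"][0],
        boundary_flank=config.boundary_flank,
    )
    report["merges.called_count"] = len(called_merges)
    subdivisions = bdyn.detect_merged_tads(
        called["knockdown"][0], called["control"][0],
        boundary_flank=config.boundary_flank,
    )
    report["subdivisions.called_count"] = len(subdivisions)
    log("dynamics", f"{comp.counts['maintained']}/{n_a} boundaries maintained")

    # -- stage 4: peak persistence ----------------------------------------
    classified = pk.classify_persistence(collection)
    for k, v in classified.counts.items():
        report[f"peaks.{k}"] = v
    # label accuracy against planted truth
    truth_ref = peak_truth[peak_truth["label"] != "gained"].reset_index(drop=True)
    truth_sorted = truth_ref.sort_values(["chrom", "start"], kind="mergesort")
    ref_rows = [(iv.chrom, iv.start, iv.end) for iv in classified.reference]
    truth_by_pos = {
        (r.chrom, r.start, r.end): r.label for r in truth_sorted.itertuples()
    }
    matched = [
        truth_by_pos.get(row) == lbl
        for row, lbl in zip(ref_rows, classified.labels)
    ]
    report["peaks.label_accuracy"] = float(np.mean(matched)) if matched else float("nan")
    gained_truth = {
        (r.chrom, r.start, r.end)
        for r in peak_truth[peak_truth["label"] == "gained"].itertuples()
    }
    gained_called = {(iv.chrom, iv.start, iv.end) for iv in classified.gained}
    report["peaks.gained_exact"] = bool(gained_truth == gained_called)

    labelled = IntervalSet(
        [
            replace(iv, name=str(lbl))
            for iv, lbl in zip(classified.reference, classified.labels)
        ],
        layout=layout, is_sorted=True,
    )
    write_bed(labelled, out / "peaks" / "reference_labelled.bed")
    write_bed(classified.gained, out / "peaks" / "gained.bed")
    classified.presence.to_csv(out / "peaks" / "presence.tsv", sep="\t", index=False)

    cfrac = pk.constitutive_fraction(classified, panel_peaks)
    for lbl, d in cfrac.items():
        report[f"constitutive.{lbl}.n"] = d["n"]
        frac = d["fraction"]
        report[f"constitutive.{lbl}.percent"] = (
            100.0 * frac if frac is not None else float("nan")
        )
    log("peaks", f"label accuracy {report['peaks.label_accuracy']}")

    # -- stage 5: conservation stratification ------------------------------
    conservation = bdyn.stratify_conservation(panel_bounds)
    conservation.to_csv(out / "enrichment" / "conservation.tsv", sep="\t", index=False)
    for stratum in ("specific", "common", "constitutive"):
        report[f"conservation.{stratum}.clusters"] = int(
            (conservation["stratum"] == stratum).sum()
        )

    # -- stage 6: enrichment ----------------------------------------------
    maintained_bounds = IntervalSet(
        [called["control"][1][i] for i, _ in comp.maintained],
        layout=layout,
    ).sorted()
    shuffle_cfg = enr.ShuffleConfig(
        n_shuffles=config.n_shuffles, max_tries=config.shuffle_max_tries,
        forbid_overlap=True, seed=scfg.seed,
    )
    enr_rows = []
    for lbl, stream in (("persistent", 31), ("lost", 32)):
        res = enr.observed_expected_ratio(
            classified.subset(lbl), maintained_bounds, layout, shuffle_cfg,
            rng=scfg.rng(stream),
        )
        report[f"obsexp.{lbl}.observed"] = res.observed
        report[f"obsexp.{lbl}.expected_mean"] = res.expected_mean
        report[f"obsexp.{lbl}.ratio"] = res.ratio
        report[f"obsexp.{lbl}.p_enrich"] = res.p_enrich
        enr_rows.append(
            {"label": lbl, "observed": res.observed,
             "expected_mean": res.expected_mean, "expected_sd": res.expected_sd,
             "ratio": res.ratio, "p_enrich": res.p_enrich,
             "p_deplete": res.p_deplete, "n_shuffles": res.n_shuffles}
        )
    pd.DataFrame(enr_rows).to_csv(
        out / "enrichment" / "obs_exp.tsv", sep="\t", index=False
    )
    log("enrichment", f"obs/exp persistent {report['obsexp.persistent.ratio']}, "
                      f"lost {report['obsexp.lost.ratio']}")

    # positional profiles at conservation strata
    strata_sets = {
        s: IntervalSet(
            [
                GenomicInterval(r.chrom, r.start, r.end)
                for r in conservation[conservation["stratum"] == s].itertuples()
            ],
            layout=layout,
        ).sorted()
        for s in ("specific", "constitutive")
    }
    prof_frames = []
    for lbl in ("persistent", "lost"):
        for stratum, anchors in strata_sets.items():
            if len(anchors) == 0:
                continue
            prof = enr.positional_profile(
                classified.subset(lbl), anchors,
                flank=config.profile_flank, profile_bin=config.profile_bin,
                layout=layout,
            )
            centre = len(prof.density) // 2
            central = prof.density[centre - 2 : centre + 3].mean()
            edge_n = max(1, len(prof.density) // 10)
            edge = np.concatenate(
                [prof.density[:edge_n], prof.density[-edge_n:]]
            ).mean()
            peak_off = int(prof.offsets[int(np.argmax(prof.density))])
            report[f"profile.{lbl}.{stratum}.central_density"] = float(central)
            report[f"profile.{lbl}.{stratum}.edge_density"] = float(edge)
            report[f"profile.{lbl}.{stratum}.peak_offset_bp"] = peak_off
            prof_frames.append(
                pd.DataFrame(
                    {"label": lbl, "stratum": stratum,
                     "offset": prof.offsets, "density": prof.density}
                )
            )
    pd.concat(prof_frames, ignore_index=True).to_csv(
        out / "enrichment" / "profiles.tsv", sep="\t", index=False
    )

    # Welch test: distance to constitutive boundary, persistent vs lost sites
    const_anchors = strata_sets["constitutive"]
    from .genome import distance_to_nearest

    d_pers = distance_to_nearest(classified.subset("persistent"), const_anchors)
    d_lost = distance_to_nearest(classified.subset("lost"), const_anchors)
    welch = enr.welch_distance_test(d_pers, d_lost)
    report["welch.distance_to_constitutive.t"] = welch["t"]
    report["welch.distance_to_constitutive.df"] = welch["df"]
    report["welch.distance_to_constitutive.p"] = welch["p"]
    report["welch.mean_distance_persistent_bp"] = float(np.nanmean(d_pers))
    report["welch.mean_distance_lost_bp"] = float(np.nanmean(d_lost))

    # housekeeping enrichment by presence count
    hk = enr.housekeeping_enrichment(
        genes, hk_flags, conservation, window=config.hk_window
    )
    hk.to_csv(out / "enrichment" / "housekeeping.tsv", sep="\t", index=False)
    for row in hk.itertuples():
        if row.k in (1, scfg.n_celltypes):
            tag = "specific" if row.k == 1 else "constitutive"
            report[f"housekeeping.{tag}.fold"] = row.fold
            report[f"housekeeping.{tag}.p_enrich_bonf"] = row.p_enrich_bonf

    # -- report ------------------------------------------------------------
    report["elapsed_recorded_in"] = "run.log"
    with open(out / "report.txt", "w") as fh:
        for k, v in report.items():
            fh.write(f"{k}\t{_fmt(v)}\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_fmt)
        fh.write("\n")
    log("done", "report written")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
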