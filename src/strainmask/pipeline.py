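"""End-to-end orchestration: simulate -> normalize -> segment -> mask/classify -> enrich.

A single YAML config drives the run. Every stage writes plain-text
outputs under the run directory and records input/output checksums, row
counts and derived seeds in a JSON manifest; re-running with unchanged
inputs skips completed stages (checksum-gated), so runs are resumable and
reproducible.

Strains whose normalized M histogram fails the bias check are flagged and
excluded from classification, Venn intersection and enrichment — the
appropriate handling for samples too divergent for population-based
normalization (outgroup-like strains).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrayio, enrich, maskclass, normalize, segment as seg_mod, simulate
from .config import CnvEvent, DyeBias, FamilySpec, SimulationConfig, VIRTUAL_CHROM

__all__ = ["RunManifest", "PipelineError", "load_config", "run_pipeline", "report"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunManifest:
    config_hash: str = ""
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, *, seed: int | None, inputs: dict, outputs: dict, rows: dict, skipped: bool = False):
        self.stages[stage] = {
            "seed": seed,
            "inputs": inputs,
            "outputs": outputs,
            "rows": rows,
            "skipped": skipped,
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(config_hash=d["config_hash"], seed=d["seed"], stages=d["stages"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(paths: list[Path]) -> dict:
    return {str(p): _sha256(p) for p in paths}


def _stage_seed(base_seed: int, stage_index: int) -> int:
    """Fan a single run seed out to per-stage seeds via a recorded derivation."""
    return int(np.random.SeedSequence([base_seed, stage_index]).generate_state(1)[0] % (2**31))


def _sim_config_from_dict(d: dict, seed: int) -> SimulationConfig:
    d = dict(d)
    if "strain_divergences" in d:
        d["strain_divergences"] = {str(k): float(v) for k, v in d["strain_divergences"].items()}
    if "family_specs" in d:
        d["family_specs"] = [FamilySpec(*f) if isinstance(f, (list, tuple)) else FamilySpec(**f) for f in d["family_specs"]]
    if "cnv_events" in d:
        d["cnv_events"] = [CnvEvent(*e) if isinstance(e, (list, tuple)) else CnvEvent(**e) for e in d["cnv_events"]]
    if "dye_bias" in d:
        d["dye_bias"] = DyeBias(**d["dye_bias"]) if isinstance(d["dye_bias"], dict) else d["dye_bias"]
    d.setdefault("seed", seed)
    return SimulationConfig(**d)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} does not contain a mapping")
    return cfg


def _maybe_skip(manifest_prev: RunManifest | None, manifest: RunManifest, stage: str, inputs: dict) -> bool:
    """True when the previous run completed this stage on identical inputs."""
    if manifest_prev is None:
        return False
    rec = manifest_prev.stages.get(stage)
    if rec is None or rec["inputs"] != inputs:
        return False
    for p, digest in rec["outputs"].items():
        path = Path(p)
        if not path.exists() or _sha256(path) != digest:
            return False
    manifest.stages[stage] = dict(rec, skipped=True)
    return True


def run_pipeline(config_path: str | Path) -> tuple[Path, RunManifest]:
    """Execute the full analysis described by a YAML config.

    Returns the run directory and the manifest. Any stage failure aborts
    with the stage name; the manifest of completed stages is saved first.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("outdir", "strainmask_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("design", "tracks", "masks", "segments", "classes", "enrichment", "report"):
        (outdir / sub).mkdir(exist_ok=True)

    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=seed)
    manifest_path = outdir / "manifest.json"
    prev = None
    if manifest_path.exists():
        try:
            prev = RunManifest.load(manifest_path)
            if prev.config_hash != cfg_hash:
                prev = None
        except (json.JSONDecodeError, KeyError):
            prev = None

    def fail(stage: str, message: str):
        manifest.save(manifest_path)
        raise PipelineError(stage, message)

    # ---- stage 0: inputs (simulate or load) -------------------------------
    stage = "simulate"
    sim_seed = _stage_seed(seed, 0)
    ann_path = outdir / "design" / "annotation.tsv"
    pos_path = outdir / "design" / "probes.pos"
    pair_paths: dict[str, dict[str, Path]] = {}
    truth_paths: dict[str, Path] = {}
    if "simulate" in cfg:
        sim_cfg = _sim_config_from_dict(cfg["simulate"] or {}, sim_seed)
        strains = sim_cfg.strains()
        for s in strains:
            pair_paths[s] = {
                "test": outdir / "design" / f"pair_{s}_test.tsv",
                "ref": outdir / "design" / f"pair_{s}_ref.tsv",
            }
            truth_paths[s] = outdir / "design" / f"truth_{s}.tsv"
        inputs = {"config": cfg_hash, "sim_seed": sim_seed}
        if not _maybe_skip(prev, manifest, stage, inputs):
            design = simulate.build_design(sim_cfg)
            arrayio.write_annotation(design, ann_path)
            arrayio.write_pos(design, pos_path)
            rows = {"probes": len(design)}
            for s in strains:
                truth = simulate.simulate_strain(design, sim_cfg, s)
                ref, test = simulate.simulate_hybridization(design, truth, sim_cfg)
                arrayio.write_pair(test, pair_paths[s]["test"])
                arrayio.write_pair(ref, pair_paths[s]["ref"])
                simulate.write_truth(truth, truth_paths[s])
            outs = [ann_path, pos_path] + [p for d in pair_paths.values() for p in d.values()] + list(truth_paths.values())
            manifest.record(stage, seed=sim_seed, inputs=inputs, outputs=_checksums(outs), rows=rows)
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("annotation", "pairs"):
            if key not in inp:
                fail(stage, f"config inputs missing {key!r}")
        ann_path = Path(inp["annotation"])
        pos_path = Path(inp["pos"]) if "pos" in inp else None
        for p in filter(None, [ann_path, pos_path]):
            if not p.exists():
                fail(stage, f"input file not found: {p}")
        for s, d in inp["pairs"].items():
            pair_paths[s] = {"test": Path(d["test"]), "ref": Path(d["ref"])}
            for p in pair_paths[s].values():
                if not p.exists():
                    fail(stage, f"input file not found: {p}")
        strains = list(pair_paths)
        manifest.record(stage, seed=None, inputs={"mode": "files"}, outputs={}, rows={})
    else:
        fail(stage, "config must contain either a 'simulate' or an 'inputs' section")

    pos = arrayio.read_pos(pos_path) if pos_path and Path(pos_path).exists() else None
    design = arrayio.read_annotation(ann_path, pos)

    # ---- stage 1: normalize + bias check ----------------------------------
    stage = "normalize"
    norm_cfg = cfg.get("normalize", {}) or {}
    norm_seed = _stage_seed(seed, 1)
    track_paths = {s: outdir / "tracks" / f"track_{s}.tsv" for s in strains}
    inputs = {
        "pairs": _checksums([p for d in pair_paths.values() for p in d.values()]),
        "params": json.dumps(norm_cfg, sort_keys=True),
        "seed": norm_seed,
    }
    diagnostics: dict[str, dict] = {}
    diag_path = outdir / "tracks" / "bias_check.json"
    tracks: dict[str, normalize.RatioTrack] = {}
    if not _maybe_skip(prev, manifest, stage, inputs):
        rows = {}
        for s in strains:
            test = arrayio.read_pair(pair_paths[s]["test"])
            ref = arrayio.read_pair(pair_paths[s]["ref"])
            raw = normalize.raw_log2(test, ref)
            raw.strain = s
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm, _pop = normalize.poplowess_normalize(
                    raw,
                    cp_alpha=float(norm_cfg.get("cp_alpha", 0.05)),
                    span=float(norm_cfg.get("span", 1 / 3)),
                    iterations=int(norm_cfg.get("iterations", 4)),
                    delta=float(norm_cfg.get("delta", 0.1)),
                    n_perm=int(norm_cfg.get("n_perm", 1000)),
                    seed=norm_seed,
                )
                diag = normalize.normalization_bias_check(norm)
            diagnostics[s] = {"mode": diag.mode, "warn": bool(diag.warn)}
            if diag.warn:
                log.warning("strain %s: normalization bias check FAILED (mode %+.2f)", s, diag.mode)
            norm.table.to_csv(track_paths[s], sep="\t", index=False)
            tracks[s] = norm
            rows[s] = len(norm)
        diag_path.write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
        manifest.record(
            stage, seed=norm_seed, inputs=inputs,
            outputs=_checksums(list(track_paths.values()) + [diag_path]), rows=rows,
        )
    else:
        diagnostics = json.loads(diag_path.read_text())
        for s in strains:
            tracks[s] = normalize.RatioTrack(pd.read_csv(track_paths[s], sep="\t"), strain=s, normalized=True)

    good_strains = [s for s in strains if not diagnostics[s]["warn"]]

    # ---- stage 2: segmentation + virtual-chromosome calibration -----------
    stage = "segment"
    seg_cfg = cfg.get("segment", {}) or {}
    seg_seed = _stage_seed(seed, 2)
    window = int(seg_cfg.get("window", 30))
    alpha = float(seg_cfg.get("alpha", 0.05))
    n_perm = int(seg_cfg.get("n_perm", 2000))
    seg_paths = {s: outdir / "segments" / f"segments_{s}.tsv" for s in good_strains}
    calib_path = outdir / "segments" / "calibration.json"
    inputs = {"tracks": _checksums([track_paths[s] for s in good_strains]), "params": json.dumps(seg_cfg, sort_keys=True), "seed": seg_seed}
    if not _maybe_skip(prev, manifest, stage, inputs):
        rows = {}
        calib_info = {}
        for s in good_strains:
            track = tracks[s]
            scan = seg_mod.sliding_window_scan(track, design, window=window)
            base = seg_mod.SegmentFilter.from_bonferroni(
                alpha=float(seg_cfg.get("filter_alpha", 0.05)),
                n_tests=max(scan.n_tests, 1),
                min_probes=int(seg_cfg.get("min_probes", 30)),
                min_abs_mean=float(seg_cfg.get("min_abs_mean", 1.0)),
            )
            candidates = [
                dataclasses.replace(base, min_abs_mean=base.min_abs_mean / 2),
                base,
                dataclasses.replace(base, min_probes=base.min_probes * 2),
            ]
            calib = seg_mod.calibrate_virtual_chromosome(track, design, candidates, alpha=alpha, n_perm=n_perm, seed=seg_seed)
            chosen = calib.chosen
            calib_info[s] = {
                "n_tests": scan.n_tests,
                "achieved_zero": calib.achieved_zero,
                "chosen": {"min_probes": chosen.min_probes, "min_abs_mean": chosen.min_abs_mean, "p_cutoff": chosen.p_cutoff},
                "false_positives": [[f.min_probes, f.min_abs_mean, n] for f, n in calib.false_positives],
            }
            m_by_probe = track.table.set_index("probe_id")["M"]
            accepted = []
            all_segments = []
            placed = design.placed()
            for chrom, grp in placed.groupby("chrom", sort=True):
                m = grp.loc[grp["probe_id"].isin(m_by_probe.index), "probe_id"].map(m_by_probe).to_numpy(float)
                if m.size < 2:
                    continue
                segs = seg_mod.cbs_segment(m, alpha=alpha, n_perm=n_perm, seed=seg_seed, chrom=chrom)
                all_segments.extend(segs)
                accepted.extend(seg_mod.filter_segments(segs, chosen))
            df = pd.DataFrame(
                [
                    {
                        "chrom": g.chrom, "start_index": g.start_index, "end_index": g.end_index,
                        "n_probes": g.n_probes, "mean_M": g.mean_M, "p_value": g.p_value,
                        "accepted": g in accepted,
                    }
                    for g in all_segments
                ]
            )
            df.to_csv(seg_paths[s], sep="\t", index=False)
            rows[s] = len(df)
        calib_path.write_text(json.dumps(calib_info, indent=2, sort_keys=True))
        manifest.record(stage, seed=seg_seed, inputs=inputs, outputs=_checksums(list(seg_paths.values()) + [calib_path]), rows=rows)

    # ---- stage 3: masks + classification + Venn ---------------------------
    stage = "classify"
    thresholds = [float(t) for t in cfg.get("mask_thresholds", [0.5, 1.0])]
    class_threshold = float(cfg.get("classify_threshold", 1.0))
    mask_paths = {(s, t): outdir / "masks" / f"mask_{s}_t{t:g}.txt" for s in good_strains for t in thresholds}
    class_paths = {s: outdir / "classes" / f"classes_{s}.tsv" for s in good_strains}
    venn_path = outdir / "classes" / "venn.json"
    retention_path = outdir / "classes" / "retention.tsv"
    inputs = {"tracks": _checksums([track_paths[s] for s in good_strains]), "thresholds": repr(sorted(thresholds) + [class_threshold])}
    if not _maybe_skip(prev, manifest, stage, inputs):
        rows = {}
        retention_rows = []
        classifications = {}
        for s in good_strains:
            track = tracks[s]
            for t in thresholds:
                mask = maskclass.build_mask_list(track, t)
                arrayio.write_mask(mask, mask_paths[(s, t)])
                retained_probes = len(track) - len(mask)
                seqs, frac = maskclass.retained_sequences(mask, design)
                retention_rows.append(
                    {
                        "strain": s, "threshold": t,
                        "probes_retained": retained_probes,
                        "probes_retained_pct": maskclass.percent(retained_probes, len(track)),
                        "sequences_retained": len(seqs),
                        "sequences_retained_pct": maskclass.percent(len(seqs), design.n_sequences),
                    }
                )
            cls = maskclass.classify_track(track, design, threshold=class_threshold)
            cls.table.to_csv(class_paths[s], sep="\t", index=False)
            classifications[s] = cls
            rows[s] = len(cls.table)
        pd.DataFrame(retention_rows).to_csv(retention_path, sep="\t", index=False)
        venn_data = {}
        if len(classifications) >= 2:
            venn = maskclass.core_conserved(classifications, design)
            venn_data = {
                "strains": venn.strains,
                "core_count": len(venn.core),
                "core_pct": maskclass.percent(len(venn.core), design.n_sequences),
                "regions": {"".join("1" if b else "0" for b in k): v for k, v in venn.regions.items()},
            }
        venn_path.write_text(json.dumps(venn_data, indent=2, sort_keys=True))
        outs = list(mask_paths.values()) + list(class_paths.values()) + [venn_path, retention_path]
        manifest.record(stage, seed=None, inputs=inputs, outputs=_checksums(outs), rows=rows)

    # ---- stage 4: enrichment ----------------------------------------------
    stage = "enrich"
    enr_cfg = cfg.get("enrich", {}) or {}
    families = list(enr_cfg.get("families", ["TE", "FCP", "GST"]))
    enr_threshold = float(enr_cfg.get("threshold", 1.0))
    enr_path = outdir / "enrichment" / "family_enrichment.tsv"
    utr_path = outdir / "enrichment" / "utr_bias.tsv"
    inputs = {"tracks": _checksums([track_paths[s] for s in good_strains]), "params": json.dumps(enr_cfg, sort_keys=True)}
    if not _maybe_skip(prev, manifest, stage, inputs):
        enr_rows, utr_rows = [], []
        for s in good_strains:
            track = tracks[s]
            prof = enrich.utr_bias_profile(track, design, threshold=enr_threshold)
            utr_rows.append(
                {
                    "strain": s, "n_probes": prof.n_probes, "n_utr": prof.n_utr,
                    "overall_utr_pct": maskclass.percent(prof.n_utr, prof.n_probes),
                    "n_variable": prof.n_variable, "n_variable_utr": prof.n_variable_utr,
                    "variable_utr_pct": maskclass.percent(prof.n_variable_utr, prof.n_variable) if prof.n_variable else float("nan"),
                    "biased": prof.biased,
                }
            )
            for fam in families:
                try:
                    r = enrich.family_enrichment(track, design, fam, threshold=enr_threshold)
                except ValueError as e:
                    fail(stage, str(e))
                enr_rows.append(dataclasses.asdict(r))
        pd.DataFrame(enr_rows).to_csv(enr_path, sep="\t", index=False)
        pd.DataFrame(utr_rows).to_csv(utr_path, sep="\t", index=False)
        manifest.record(stage, seed=None, inputs=inputs, outputs=_checksums([enr_path, utr_path]), rows={"families": len(enr_rows)})

    manifest.save(manifest_path)
    return outdir, manifest


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str | Path) -> Path:
    """Write a human-readable summary (text + histogram figures) for a run.

    Incomplete runs produce a partial report with the gaps flagged.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    rep_dir = run_dir / "report"
    rep_dir.mkdir(exist_ok=True)
    lines: list[str] = ["strainmask run report", "=" * 40, ""]

    diag_path = run_dir / "tracks" / "bias_check.json"
    diagnostics = json.loads(diag_path.read_text()) if diag_path.exists() else {}
    track_files = sorted((run_dir / "tracks").glob("track_*.tsv"))
    if not track_files:
        lines.append("[missing] no normalized tracks found")
    for tf in track_files:
        strain = tf.stem.removeprefix("track_")
        df = pd.read_csv(tf, sep="\t")
        m = df["M"].to_numpy(float)
        sd = float(np.std(m, ddof=1))
        hist = normalize.histogram_m(m, 0.2)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(hist["center"], hist["count"], width=0.18)
        ax.set_xlabel("normalized log2-ratio M (0.2 bins)")
        ax.set_ylabel("probes")
        ax.set_title(f"{strain}: SD={sd:.2f}")
        fig.tight_layout()
        fig.savefig(rep_dir / f"hist_{strain}.png", dpi=100)
        plt.close(fig)
        d = diagnostics.get(strain, {})
        flag = "  ** BIAS WARNING: normalization unreliable **" if d.get("warn") else ""
        lines.append(f"strain {strain}: {len(df)} probes, SD(M) = {sd:.2f}, histogram mode {d.get('mode', float('nan')):+.1f}{flag}")
    lines.append("")

    ret_path = run_dir / "classes" / "retention.tsv"
    if ret_path.exists():
        lines.append("Probe/sequence retention after masking:")
        lines.append(pd.read_csv(ret_path, sep="\t").to_string(index=False))
    else:
        lines.append("[missing] retention table")
    lines.append("")

    venn_path = run_dir / "classes" / "venn.json"
    if venn_path.exists():
        venn = json.loads(venn_path.read_text())
        if venn:
            lines.append(f"Conserved-sequence Venn over strains {venn['strains']}:")
            lines.append(f"  core (conserved in all): {venn['core_count']} sequences ({venn['core_pct']:g}%)")
            for key, count in sorted(venn["regions"].items()):
                members = [s for s, b in zip(venn["strains"], key) if b == "1"]
                lines.append(f"  {'+'.join(members)}: {count}")
    lines.append("")

    seg_files = sorted((run_dir / "segments").glob("segments_*.tsv"))
    lines.append("Accepted copy-number segments:")
    any_acc = False
    for sf in seg_files:
        strain = sf.stem.removeprefix("segments_")
        df = pd.read_csv(sf, sep="\t")
        acc = df[df["accepted"]] if "accepted" in df.columns else df.iloc[0:0]
        for _, r in acc.iterrows():
            any_acc = True
            lines.append(
                f"  {strain} {r['chrom']}[{int(r['start_index'])}:{int(r['end_index'])}] "
                f"n={int(r['n_probes'])} mean M={r['mean_M']:+.2f} p={r['p_value']:.2e}"
            )
    if not any_acc:
        lines.append("  none")
    lines.append("")

    enr_path = run_dir / "enrichment" / "family_enrichment.tsv"
    if enr_path.exists():
        lines.append("Family variability enrichment (binomial vs all / vs UTR-only background):")
        lines.append(pd.read_csv(enr_path, sep="\t").to_string(index=False))
    else:
        lines.append("[missing] enrichment table")

    out = rep_dir / "report.txt"
    out.write_text("\n".join(lines) + "\n")
    return out
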