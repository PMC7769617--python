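"""End-to-end orchestration of the synthetic/real analysis.

``run`` executes the stages in dependency order — simulate → variants →
overlap → diff → cnn → knockout — from a single config mapping, writes each
stage's tables under the output directory, and records a manifest with a
SHA-256 hash per output file plus the config echo and package version.
Rerunning with the same config and seed reproduces the hashes of every
deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cnn as cnn_mod
from . import mutagenesis as mut_mod
from .diffbind import correlate_differential, differential_test, six_class_labels
from .motifs import (FORKHEAD_KMERS, GATA, HOX_PBX, count_variants,
                     cross_class_exclusion, select_candidate_sites,
                     select_knockout_pairs)
from .synth import SynthConfig, generate, truth_check

STAGES = ("simulate", "variants", "overlap", "diff", "cnn", "knockout")

__all__ = ["STAGES", "run"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: dict):
    if "seed" not in config:
        raise ValueError("config must set a seed")
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for dep, needs in {"variants": "simulate", "overlap": "simulate",
                       "diff": "simulate", "cnn": "simulate",
                       "knockout": "cnn"}.items():
        if dep in stages and needs not in stages:
            raise ValueError(f"stage {dep!r} requires stage {needs!r}")
    return stages


def run(config: dict, outdir) -> dict:
    """Execute the configured stages; returns the manifest mapping.

    ``config`` keys: ``seed`` (required), ``stages`` (subset of STAGES, in
    any order), ``synth`` (SynthConfig overrides), ``variants``/``diff``/
    ``cnn``/``knockout`` stage parameter mappings.
    """
    stages = _validate(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"version": __version__, "seed": seed, "stages": [],
                "files": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    log_lines = []

    def _log(msg):
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def _register(name, path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    with open(out / "config_echo.json", "w") as fh:
        json.dump(config, fh, indent=2, default=str)
    _register("config_echo", out / "config_echo.json")

    bundle = None
    model = None
    rng_root = np.random.SeedSequence(seed)
    sub = {name: int(s.generate_state(1)[0] % (2 ** 31))
           for name, s in zip(STAGES, rng_root.spawn(len(STAGES)))}

    try:
        if "simulate" in stages:
            _log("stage simulate")
            synth_kw = dict(config.get("synth", {}))
            bundle = generate(SynthConfig(seed=sub["simulate"], **synth_kw))
            report = truth_check(bundle)
            if not report.ok:
                raise RuntimeError(f"simulate: truth check failed: "
                                   f"{report.failures[:3]}")
            paths = bundle.write(out / "simulate")
            for k, p in paths.items():
                _register(f"simulate/{k}", p)
            manifest["stages"].append("simulate")

        if "variants" in stages:
            _log("stage variants")
            kw = config.get("variants", {})
            top = int(kw.get("top", 250))
            bin_size = int(kw.get("bin_size", 50))
            tabs = {}
            for name in ("HOXA3_PBA_r1", "HOXA2_BA2_r1"):
                ps = bundle.peaksets[name].ranked()
                top_n = min(top, len(ps))
                ranked = ps.top(top_n)
                id_to_seq = dict(zip(bundle.region_ids,
                                     bundle.summit_sequences()))
                seqs = [id_to_seq[p.name] for p in ranked]
                tabs[name] = count_variants(ranked, seqs, bin_size=bin_size)
            vdir = out / "variants"
            vdir.mkdir(exist_ok=True)
            for name, tab in tabs.items():
                p = vdir / f"variant_counts_{name}.tsv"
                tab.counts.to_csv(p, sep="\t")
                _register(f"variants/counts_{name}", p)
            diff = (tabs["HOXA3_PBA_r1"].presence
                    - tabs["HOXA2_BA2_r1"].presence).sort_values(ascending=False)
            p = vdir / "presence_difference.tsv"
            diff.to_csv(p, sep="\t", header=["presence_diff"])
            _register("variants/presence_difference", p)
            manifest["stages"].append("variants")

        if "overlap" in stages:
            _log("stage overlap")
            from .intervals import ranked_overlap_curve
            a = bundle.peaksets["HOXA3_PBA_r1"].ranked()
            b = bundle.peaksets["HOXA2_BA2_r1"].ranked()
            nmax = min(len(a), len(b))
            Ns = [n for n in (50, 100, 250, 500, 1000) if n <= nmax] or [nmax]
            curve = ranked_overlap_curve(a, b, Ns)
            p = out / "overlap_curve.tsv"
            curve.to_csv(p, sep="\t", index=False)
            _register("overlap/curve", p)
            manifest["stages"].append("overlap")

        if "diff" in stages:
            _log("stage diff")
            kw = config.get("diff", {})
            contrasts = {}
            for pair in (("PBA", "BA2"), ("PBA", "BA1"), ("BA2", "BA1")):
                contrasts[pair] = differential_test(
                    bundle.counts, pair, factor="MEIS",
                    lfc_threshold=float(kw.get("lfc", 1.0)),
                    fdr=float(kw.get("fdr", 0.05)))
            labels = six_class_labels(contrasts)
            main = contrasts[("PBA", "BA2")].table.copy()
            main["class"] = labels.to_numpy()
            main.insert(0, "region_id", bundle.region_ids)
            p = out / "differential.tsv"
            main.to_csv(p, sep="\t", index=False)
            _register("diff/differential", p)
            ac_lfc = np.log2((bundle.acetyl_counts["PBA"] + 0.5)
                             / (bundle.acetyl_counts["BA2"] + 0.5)).to_numpy()
            r, nr = correlate_differential(main["lfc"].to_numpy(), ac_lfc,
                                           lfc_filter=float(kw.get("lfc_filter", 1.0)))
            with open(out / "diff_summary.json", "w") as fh:
                json.dump({"acetylation_correlation": r, "n": nr,
                           "class_counts": labels.value_counts().to_dict()}, fh)
            _register("diff/summary", out / "diff_summary.json")
            manifest["stages"].append("diff")

        if "cnn" in stages:
            _log("stage cnn")
            kw = config.get("cnn", {})
            model = cnn_mod.build()
            Y = bundle.observed_log2_rpkm()
            cnn_mod.train(model, bundle.sequences, Y,
                          epochs=int(kw.get("epochs", 250)),
                          lr=float(kw.get("lr", 3e-2)),
                          batch=int(kw.get("batch", 64)),
                          seed=sub["cnn"])
            ck = out / "model.ckpt.json"
            cnn_mod.save_checkpoint(model, ck)
            _register("cnn/checkpoint", ck)
            with open(out / "cnn_log.json", "w") as fh:
                json.dump(model.training_log, fh)
            _register("cnn/log", out / "cnn_log.json")
            manifest["stages"].append("cnn")

        if "knockout" in stages:
            _log("stage knockout")
            kw = config.get("knockout", {})
            rids, seqs = bundle.region_ids, bundle.sequences
            hox = select_candidate_sites(rids, seqs, HOX_PBX,
                                         exclude_internal=None)
            seq_of = dict(zip(rids, seqs))
            n_sites = int(kw.get("n_sites", 50))
            results = []
            for motif, cls in ((FORKHEAD_KMERS, "forkhead"), (GATA, "gata")):
                sites = select_candidate_sites(
                    rids, seqs, motif,
                    exclude_internal=cross_class_exclusion(cls))
                pairs = select_knockout_pairs(hox, sites)
                for k, (_, row) in enumerate(pairs.iterrows()):
                    if k >= n_sites:
                        break
                    hit = mut_mod.MotifHit(row["region_id"], int(row["offset"]),
                                           row["strand"], row["matched_variant"],
                                           0, cls, int(row["end"] - row["offset"]))
                    site = mut_mod.make_site(hit, bundle.config.region_width,
                                             feature_class=cls)
                    region_seq = seq_of[row["region_id"]]
                    ctrl = mut_mod.make_control_site(
                        region_seq, site, seed=sub["knockout"] + k)
                    results.append(mut_mod.knockout(
                        model, region_seq, site,
                        repeats=int(kw.get("repeats", 100)),
                        seed=sub["knockout"] + k, control_site=ctrl))
            summary = (mut_mod.cohort_summary(results) if results
                       else pd.DataFrame())
            p = out / "knockout_summary.tsv"
            summary.to_csv(p, sep="\t", index=False)
            _register("knockout/summary", p)
            manifest["stages"].append("knockout")
    except Exception as exc:
        _log(f"FAILED: {exc}")
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed in stage sequence "
                           f"{manifest['stages']}: {exc}") from exc

    _log("done")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
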