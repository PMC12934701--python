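"""End-to-end study orchestration: simulate -> statistics/images ->
stratify/split -> fit ABC / DNN / CNN -> benchmark report.

A :class:`StudyConfig` fully determines a run (scenarios, scale profile,
counts, seeds, models).  ``run_study`` executes the stages in order inside an
output directory, records completed stages in a ``stages.json`` manifest
keyed by a hash of the resolved configuration, and skips stages whose
outputs already exist for the same configuration, so interrupted runs
resume where they stopped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import abc as abcmod
from . import nets
from .evaluate import (
    DatasetSplit,
    benchmark_report,
    partial_r2,
    split_dataset,
    stratify_uniform,
)
from .imaging import IMAGE_WIDTH, encode_image
from .simulate import (
    DESK_PROFILE,
    FULL_PROFILE,
    ScaleProfile,
    sample_parameters,
    simulate_sweep,
)
from .sumstats import STAT_NAMES, compute_all, window_from_result
from .vcfio import build_manifest, write_manifest, write_vcf

__all__ = ["StudyConfig", "run_study", "simulate_scenario"]

PROFILES = {"full": FULL_PROFILE, "desk": DESK_PROFILE}


@dataclass
class StudyConfig:
    scenarios: tuple = ("constant", "growth")
    n_sims: int = 2000
    profile: str = "desk"
    seed: int = 1
    burn_in: str = "coalescent"  # or "forward"
    models: tuple = ("abc", "dnn")  # any of abc / dnn / cnn
    min_bin_fraction: float = 0.5  # dense-tf-span rule for stratification
    tune_iters: int = 60
    mc_passes: int = 100
    max_snps: int = IMAGE_WIDTH
    max_attempts: int = 1000
    write_vcfs: bool = False
    # optional overrides of the named profile
    NA_range: Optional[tuple] = None
    L: Optional[int] = None
    n: Optional[int] = None
    burn_in_factor: Optional[float] = None

    def resolve_profile(self) -> ScaleProfile:
        base = PROFILES[self.profile]
        changes = {}
        if self.NA_range is not None:
            changes["NA_range"] = tuple(self.NA_range)
        if self.L is not None:
            changes["L"] = self.L
        if self.n is not None:
            changes["n"] = self.n
        if self.burn_in_factor is not None:
            changes["burn_in_factor"] = self.burn_in_factor
        return dataclasses.replace(base, **changes) if changes else base

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_done(out_dir, stage, cfg_hash) -> bool:
    path = os.path.join(out_dir, "stages.json")
    if not os.path.exists(path):
        return False
    with open(path) as fh:
        manifest = json.load(fh)
    entry = manifest.get(stage)
    return bool(entry) and entry.get("config_hash") == cfg_hash and all(
        os.path.exists(os.path.join(out_dir, f)) for f in entry.get("outputs", [])
    )


def _mark_stage(out_dir, stage, cfg_hash, outputs, seed):
    path = os.path.join(out_dir, "stages.json")
    manifest = {}
    if os.path.exists(path):
        with open(path) as fh:
            manifest = json.load(fh)
    manifest[stage] = {"config_hash": cfg_hash, "outputs": outputs, "seed": seed}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_scenario(
    scenario: str,
    n_sims: int,
    seed: int,
    profile: ScaleProfile,
    burn_in: str = "coalescent",
    max_snps: int = IMAGE_WIDTH,
    max_attempts: int = 1000,
    keep_images: bool = False,
    vcf_dir: Optional[str] = None,
    burn_in_factor: Optional[float] = None,
):
    """Simulate `n_sims` replicates of one scenario and compute per-replicate
    statistics (and optionally images).

    Returns (manifest DataFrame, stats DataFrame, images dict or None).
    The stats table carries the 17 raw statistics, the validity flag, and
    the recorded tf / ta per completed simulation.
    """
    rng = np.random.default_rng(seed)
    records = []
    stat_rows = []
    images = {} if keep_images else None
    for i in range(n_sims):
        params = sample_parameters(scenario, rng, profile)
        result = simulate_sweep(
            params, burn_in=burn_in, burn_in_factor=burn_in_factor,
            max_attempts=max_attempts,
        )
        sim_id = f"{scenario}_{i:06d}"
        records.append((sim_id, result))
        if result.status != "complete":
            continue
        if vcf_dir is not None:
            write_vcf(result, os.path.join(vcf_dir, f"{sim_id}.vcf"))
        win = window_from_result(result, max_snps=max_snps)
        vec = compute_all(win)
        row = {"sim_id": sim_id, **vec.as_dict(), "tf": result.tf, "ta": result.ta}
        stat_rows.append(row)
        if keep_images and vec.valid and win.S >= 2:
            img = encode_image(win)
            images[sim_id] = (img.pixels, img.positions)
    manifest = build_manifest(records)
    stats = pd.DataFrame(
        stat_rows, columns=["sim_id", *STAT_NAMES, "valid", "tf", "ta"]
    )
    return manifest, stats, images


def _valid_stats(stats: pd.DataFrame) -> pd.DataFrame:
    return stats[stats["valid"].astype(bool)].reset_index(drop=True)


def _subset(stats: pd.DataFrame, ids) -> pd.DataFrame:
    sub = stats[stats["sim_id"].isin(set(ids))]
    return sub.sort_values("sim_id").reset_index(drop=True)


def _abc_stage(stats, split, seed):
    train = _subset(stats, split.train)
    val = _subset(stats, split.validation)
    test = _subset(stats, split.test)
    X = abcmod.stats_matrix
    y = lambda t: np.log10(t["tf"].to_numpy(dtype=float))
    best, scores = abcmod.grid_search(X(train), y(train), X(val), y(val))
    tr, te, _ = abcmod.normalize_stats(X(train), X(test))
    preds = abcmod.predict_batch(te, tr, y(train), best)
    table = pd.DataFrame({
        "sim_id": test["sim_id"], "truth": y(test), "prediction": preds,
        "ta": test["ta"].to_numpy(dtype=float),
    })
    return best, scores, table


def _net_stage(family, stats, split, images, seed, tune_iters, mc_passes):
    rng = np.random.default_rng(seed)
    train = _subset(stats, split.train)
    val = _subset(stats, split.validation)
    test = _subset(stats, split.test)
    y = lambda t: np.log10(t["tf"].to_numpy(dtype=float))
    if family == "dnn":
        mean, sd = nets.standardize_fit(
            abcmod.stats_matrix(train)
        )
        mk = lambda t: nets.standardize_apply(abcmod.stats_matrix(t), mean, sd)
        tr_in, va_in, te_in = mk(train), mk(val), mk(test)
    else:
        def mk(t):
            pix = np.stack([images[sid][0] for sid in t["sim_id"]])
            pos = np.stack([images[sid][1] for sid in t["sim_id"]])
            return pix, pos

        # CNN sets are restricted to simulations with an image encoding
        train = train[train["sim_id"].isin(images)].reset_index(drop=True)
        val = val[val["sim_id"].isin(images)].reset_index(drop=True)
        test = test[test["sim_id"].isin(images)].reset_index(drop=True)
        tr_in, va_in, te_in = mk(train), mk(val), mk(test)
    hp, trials = nets.tune(
        family, tr_in, y(train), va_in, y(val), iterations=tune_iters, rng=rng
    )
    model = nets.CNN(hp, rng) if family == "cnn" else nets.DNN(hp, rng)
    model, info = nets.train_final(model, tr_in, y(train), va_in, y(val), rng=rng)
    recs = nets.predict_mc(
        model, te_in, passes=mc_passes, rng=rng,
        sim_ids=test["sim_id"].tolist(), truths=y(test),
    )
    table = pd.DataFrame({
        "sim_id": [r.sim_id for r in recs],
        "truth": [r.truth for r in recs],
        "prediction": [r.point for r in recs],
        "sd": [r.sd for r in recs],
        "ta": test["ta"].to_numpy(dtype=float),
    })
    return hp, trials, table, info


def run_study(config: StudyConfig, out_dir: str) -> str:
    """Execute the full study pipeline under `out_dir`; returns the report
    directory.  Stages already completed for this configuration are
    skipped."""
    os.makedirs(out_dir, exist_ok=True)
    cfg_hash = config.config_hash()
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True, default=str)
    profile = config.resolve_profile()
    root_seq = np.random.SeedSequence(config.seed)
    scen_seeds = {
        sc: int(s.generate_state(1)[0] % (2**31))
        for sc, s in zip(config.scenarios, root_seq.spawn(len(config.scenarios)))
    }

    for scenario in config.scenarios:
        sdir = os.path.join(out_dir, scenario)
        os.makedirs(sdir, exist_ok=True)
        need_images = "cnn" in config.models
        stage = f"simulate:{scenario}"
        outputs = [f"{scenario}/manifest.tsv", f"{scenario}/stats.tsv"]
        if need_images:
            outputs.append(f"{scenario}/images.npz")
        if not _stage_done(out_dir, stage, cfg_hash):
            vcf_dir = None
            if config.write_vcfs:
                vcf_dir = os.path.join(sdir, "vcf")
                os.makedirs(vcf_dir, exist_ok=True)
            manifest, stats, images = simulate_scenario(
                scenario, config.n_sims, scen_seeds[scenario], profile,
                burn_in=config.burn_in, max_snps=config.max_snps,
                max_attempts=config.max_attempts, keep_images=need_images,
                vcf_dir=vcf_dir, burn_in_factor=profile.burn_in_factor,
            )
            write_manifest(manifest, os.path.join(sdir, "manifest.tsv"))
            stats.to_csv(os.path.join(sdir, "stats.tsv"), sep="\t", index=False)
            if need_images:
                np.savez_compressed(
                    os.path.join(sdir, "images.npz"),
                    ids=np.array(list(images)),
                    pixels=np.stack([v[0] for v in images.values()])
                    if images else np.zeros((0, 0, 0)),
                    positions=np.stack([v[1] for v in images.values()])
                    if images else np.zeros((0, 0)),
                )
            _mark_stage(out_dir, stage, cfg_hash, outputs, scen_seeds[scenario])

        stats = pd.read_csv(os.path.join(sdir, "stats.tsv"), sep="\t")
        manifest = pd.read_csv(os.path.join(sdir, "manifest.tsv"), sep="\t")
        images = None
        if need_images:
            with np.load(os.path.join(sdir, "images.npz")) as z:
                images = {
                    sid: (z["pixels"][i], z["positions"][i])
                    for i, sid in enumerate(z["ids"])
                }

        stage = f"split:{scenario}"
        if not _stage_done(out_dir, stage, cfg_hash):
            rng = np.random.default_rng(scen_seeds[scenario] + 1)
            valid = _valid_stats(stats)
            retained = stratify_uniform(
                manifest[manifest["sim_id"].isin(set(valid["sim_id"]))], rng,
                min_bin_fraction=config.min_bin_fraction,
            )
            split = split_dataset(retained, rng)
            with open(os.path.join(sdir, "splits.json"), "w") as fh:
                json.dump(
                    {"train": split.train, "validation": split.validation,
                     "test": split.test}, fh,
                )
            _mark_stage(out_dir, stage, cfg_hash,
                        [f"{scenario}/splits.json"], scen_seeds[scenario] + 1)
        with open(os.path.join(sdir, "splits.json")) as fh:
            sp = json.load(fh)
        split = DatasetSplit(
            train=sp["train"], validation=sp["validation"], test=sp["test"]
        )
        valid = _valid_stats(stats)

        preds = {}
        if "abc" in config.models:
            stage = f"abc:{scenario}"
            if not _stage_done(out_dir, stage, cfg_hash):
                best, scores, table = _abc_stage(valid, split, scen_seeds[scenario])
                scores.to_csv(os.path.join(sdir, "abc_grid.tsv"), sep="\t", index=False)
                table.to_csv(os.path.join(sdir, "abc_preds.tsv"), sep="\t", index=False)
                _mark_stage(out_dir, stage, cfg_hash,
                            [f"{scenario}/abc_grid.tsv", f"{scenario}/abc_preds.tsv"],
                            scen_seeds[scenario])
            preds["abc"] = pd.read_csv(os.path.join(sdir, "abc_preds.tsv"), sep="\t")

        for family in ("dnn", "cnn"):
            if family not in config.models:
                continue
            stage = f"{family}:{scenario}"
            if not _stage_done(out_dir, stage, cfg_hash):
                hp, trials, table, info = _net_stage(
                    family, valid, split, images, scen_seeds[scenario] + 2,
                    config.tune_iters, config.mc_passes,
                )
                trials.to_csv(
                    os.path.join(sdir, f"{family}_trials.tsv"), sep="\t", index=False
                )
                table.to_csv(
                    os.path.join(sdir, f"{family}_preds.tsv"), sep="\t", index=False
                )
                _mark_stage(out_dir, stage, cfg_hash,
                            [f"{scenario}/{family}_trials.tsv",
                             f"{scenario}/{family}_preds.tsv"],
                            scen_seeds[scenario] + 2)
            preds[family] = pd.read_csv(
                os.path.join(sdir, f"{family}_preds.tsv"), sep="\t"
            )

        stage = f"report:{scenario}"
        if not _stage_done(out_dir, stage, cfg_hash):
            train_stats = _subset(valid, split.train)
            pr2 = partial_r2(train_stats)
            pr2.partial_r2.rename("partial_r2").to_csv(
                os.path.join(sdir, "partial_r2.tsv"), sep="\t",
                index_label="statistic",
            )
            if preds:
                # restrict every model to the common test set (the CNN skips
                # records without an image encoding)
                common = set.intersection(
                    *(set(t["sim_id"].astype(str)) for t in preds.values())
                )
                preds_common = {
                    name: t[t["sim_id"].astype(str).isin(common)]
                    .sort_values("sim_id").reset_index(drop=True)
                    for name, t in preds.items()
                }
                report, errors = benchmark_report(preds_common)
                report.to_csv(os.path.join(sdir, "report.tsv"), sep="\t", index=False)
                errors.to_csv(os.path.join(sdir, "errors.tsv"), sep="\t", index=False)
            _mark_stage(out_dir, stage, cfg_hash,
                        [f"{scenario}/partial_r2.tsv"], scen_seeds[scenario])
    return out_dir
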