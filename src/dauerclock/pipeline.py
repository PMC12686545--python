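"""End-to-end pipeline: simulate (optional) -> filter -> normalize ->
clocks -> trend -> clustering -> overlap -> enrichment -> UV/GLTD.

The pipeline is driven by a declarative :class:`PipelineConfig` (YAML
on disk) and writes every stage's table plus a JSON run manifest with
input paths, seeds and a SHA-256 hash per output file, so that two runs
with the same config can be compared hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clock as clock_mod
from . import containers, enrichment, gltd, stochastic, synthetic, trend

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    When ``counts`` is empty the synthetic generator provides the data
    (and the ground-truth program gene sets double as the enrichment
    collection); otherwise counts/metadata/genes/GMT paths must point at
    files on disk.
    """

    out_dir: str = "dauerclock_run"
    counts: str = ""
    metadata: str = ""
    genes: str = ""
    gmt: str = ""
    simulate: bool = True
    seed: int = 0
    alpha: float = 0.05
    min_count: int = 10
    min_samples: int = 3
    k_min: int = 1
    k_max: int = 8
    kmeans_n_init: int = 100
    kmeans_max_iter: int = 1000
    clock_cv_folds: int = 5
    stochastic_n_genes: int = 25
    run_clock: bool = True
    run_stochastic: bool = True
    run_trend: bool = True
    run_cluster: bool = True
    run_overlap: bool = True
    run_enrichment: bool = True
    run_gltd: bool = True
    uv_dose: float = 1.0
    lesion_rate_per_kb_per_dose: float = 0.1
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        if not self.simulate:
            for fieldname in ("counts", "metadata", "genes"):
                path = getattr(self, fieldname)
                if not path:
                    raise ValueError(f"config field {fieldname!r} is required "
                                     "when simulate is off")
                if not Path(path).exists():
                    raise FileNotFoundError(
                        f"config field {fieldname!r}: file not found: {path}"
                    )
            if self.run_enrichment and not self.gmt:
                raise ValueError("config field 'gmt' is required for enrichment "
                                 "when simulate is off")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": {},
        "outputs": {},
        "skipped": [],
    }
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s: start", name)
        manifest["stages"][name] = {"started": time.time()}

    def done(name):
        rec = manifest["stages"][name]
        rec["wall_s"] = round(time.time() - rec.pop("started"), 3)
        logger.info("stage %s: done (%.2fs)", name, rec["wall_s"])

    truth = None
    gene_sets = None
    try:
        # ---- inputs -------------------------------------------------
        if config.simulate:
            stage("simulate")
            cfg = synthetic.SimulationConfig(seed=config.seed, **config.sim_overrides)
            counts, metadata, truth = synthetic.simulate_timecourse(cfg)
            paths = synthetic.write_fixture(out / "fixture", counts, metadata, truth)
            outputs.update({f"fixture_{k}": v for k, v in paths.items()})
            genes_frame = truth.table[["gene_id", "length_bp"]]
            gene_sets = synthetic.program_gene_sets(truth)
            done("simulate")
        else:
            stage("load")
            counts = containers.read_counts(config.counts)
            metadata = containers.read_metadata(config.metadata)
            genes_frame = containers.read_genes(config.genes)
            if config.gmt:
                gene_sets = enrichment.read_gmt(config.gmt)
            done("load")

        # ---- filtering & normalization ------------------------------
        stage("prefilter")
        filtered = trend.prefilter(counts, config.min_count, config.min_samples)
        _write(filtered, out / "filtered_counts.tsv", outputs, "filtered_counts")
        done("prefilter")

        stage("normalize")
        norm, factors = trend.normalize_counts(filtered)
        factors.rename_axis("sample_id").to_frame().to_csv(
            out / "size_factors.tsv", sep="\t"
        )
        outputs["size_factors"] = out / "size_factors.tsv"
        done("normalize")

        times = metadata.set_index("sample_id").loc[
            list(counts.columns), "timepoint_h"
        ]

        # ---- clocks -------------------------------------------------
        if config.run_clock:
            stage("clock")
            model = clock_mod.BinarizedClock.from_counts(filtered, metadata).fit(
                cv_folds=min(config.clock_cv_folds, filtered.shape[1]),
                seed=config.seed,
            )
            model.to_json(out / "clock.json")
            outputs["clock_model"] = out / "clock.json"
            pba = model.predict(clock_mod.binarize(filtered))
            pba.rename_axis("sample_id").to_frame().to_csv(out / "pba.tsv", sep="\t")
            outputs["pba"] = out / "pba.tsv"
            done("clock")
        else:
            manifest["skipped"].append("clock")

        if config.run_stochastic:
            stage("stochastic")
            stoch = stochastic.select_clock_genes(
                filtered, times, n_genes=config.stochastic_n_genes
            )
            stoch.to_json(out / "stochastic_clock.json")
            outputs["stochastic_model"] = out / "stochastic_clock.json"
            scores = stochastic.score_matrix(filtered, stoch)
            scores.rename_axis("sample_id").to_frame().to_csv(
                out / "stochastic_scores.tsv", sep="\t"
            )
            outputs["stochastic_scores"] = out / "stochastic_scores.tsv"
            done("stochastic")
        else:
            manifest["skipped"].append("stochastic")

        # ---- trend DE + clustering + overlap ------------------------
        trend_frame = None
        if config.run_trend:
            stage("trend")
            days = times / 24.0
            trend_frame = trend.trend_test(norm, days, alpha=config.alpha)
            _write(trend_frame, out / "trend.tsv", outputs, "trend", index=True)
            done("trend")
        else:
            manifest["skipped"].append("trend")

        if config.run_cluster:
            stage("cluster")
            assignment = trend.cluster_profiles(
                norm,
                times,
                k_range=range(config.k_min, config.k_max + 1),
                seed=config.seed,
                n_init=config.kmeans_n_init,
                max_iter=config.kmeans_max_iter,
            )
            assignment.labels.rename_axis("gene_id").to_frame().to_csv(
                out / "clusters.tsv", sep="\t"
            )
            assignment.wcss.rename_axis("k").to_frame().to_csv(
                out / "wcss.tsv", sep="\t"
            )
            outputs["clusters"] = out / "clusters.tsv"
            outputs["wcss"] = out / "wcss.tsv"
            manifest["chosen_k"] = assignment.chosen_k
            done("cluster")
        else:
            manifest["skipped"].append("cluster")

        if config.run_overlap and trend_frame is not None:
            stage("overlap")
            # two signatures: trend on the full course vs the course
            # without its final timepoint, a within-run concordance check
            tmax = times.max()
            keep = times[times < tmax].index
            sub = trend.trend_test(norm[keep], times.loc[keep] / 24.0, config.alpha)
            full_set = _signed(trend_frame)
            sub_set = _signed(sub)
            overlap = trend.exit_overlap({"full_course": full_set, "truncated": sub_set})
            _write(overlap, out / "overlap.tsv", outputs, "overlap")
            done("overlap")
        elif config.run_overlap:
            manifest["skipped"].append("overlap (needs trend)")
        else:
            manifest["skipped"].append("overlap")

        # ---- enrichment ---------------------------------------------
        if config.run_enrichment and trend_frame is not None and gene_sets is not None:
            stage("enrichment")
            universe = list(filtered.index)
            query = trend_frame.index[trend_frame["direction"] != "ns"].tolist()
            if query:
                enr = enrichment.ora(query, gene_sets, universe)
                _write(enr, out / "enrichment.tsv", outputs, "enrichment")
            else:
                logger.warning("no significant genes; enrichment skipped")
                manifest["skipped"].append("enrichment (no significant genes)")
            done("enrichment")
        elif not config.run_enrichment:
            manifest["skipped"].append("enrichment")
        else:
            manifest["skipped"].append("enrichment (missing inputs)")

        # ---- UV / GLTD ----------------------------------------------
        if config.run_gltd and config.simulate and truth is not None:
            stage("gltd")
            uv_counts = synthetic.apply_uv_effect(
                counts,
                truth,
                dose=config.uv_dose,
                lesion_rate_per_kb_per_dose=config.lesion_rate_per_kb_per_dose,
                seed=config.seed + 1,
            )
            merged = pd.concat(
                [counts.add_suffix("_ctl"), uv_counts.add_suffix("_uv")], axis=1
            )
            merged_f = trend.prefilter(merged, config.min_count, config.min_samples)
            merged_n, _ = trend.normalize_counts(merged_f)
            ctl = [c for c in merged_n.columns if c.endswith("_ctl")]
            uv = [c for c in merged_n.columns if c.endswith("_uv")]
            de = trend.two_group_test(merged_n, ctl, uv, alpha=config.alpha)
            up = de.index[de["direction"] == "up"].tolist()
            down = de.index[de["direction"] == "down"].tolist()
            lengths = containers.gene_lengths(genes_frame)
            if up and down:
                res = gltd.gltd_test(up, down, lengths)
                (out / "gltd.tsv").write_text(
                    "n_up\tn_down\tmedian_length_up\tmedian_length_down\tU\tp\tdirection\n"
                    f"{res.n_up}\t{res.n_down}\t{res.median_length_up}\t"
                    f"{res.median_length_down}\t{res.u_statistic}\t{res.p}\t"
                    f"{res.direction}\n"
                )
                outputs["gltd"] = out / "gltd.tsv"
            else:
                manifest["skipped"].append("gltd (no signed DEGs)")
            done("gltd")
        elif config.run_gltd:
            manifest["skipped"].append("gltd (needs simulated truth)")
        else:
            manifest["skipped"].append("gltd")
    except Exception as exc:
        failed = next(
            (n for n, rec in manifest["stages"].items() if "started" in rec), "?"
        )
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    for name, path in outputs.items():
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"stage output {name} missing or empty: {path}")
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _signed(frame: pd.DataFrame) -> dict[str, int]:
    sig = frame[frame["direction"] != "ns"]
    return {g: (1 if s > 0 else -1) for g, s in sig["slope"].items()}


def _write(frame, path: Path, outputs: dict, name: str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
    outputs[name] = path
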