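"""End-to-end orchestration with a reproducibility manifest.

A run executes, in dependency order: simulate (or load) -> validate ->
fit the selected model specs -> WAIC ranking -> posterior-predictive
summaries -> sister-pair analysis -> tree rendering.  Every run writes a
manifest (seeds, priors, package version, input digest, artifact digests)
sufficient to re-execute it bit-identically; stages are idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .data import read_tidy, validate, write_tidy
from .design import design_matrix
from .model import LineageFateModel
from .pairs import chisq_2x2, compare_pairs, event_probability, find_matched_pairs, pair_table
from .prediction import duration_quartiles_iqr
from .simulate import GenParams, simulate_dataset
from .trees import abnormality_percentages, build_trees
from .viz import render_gallery
from .waic import rank_models

log = logging.getLogger("lineagefate")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "lineagefate_run"
    input_path: str | None = None  # tidy CSV; None -> simulate
    gen_params: GenParams = field(default_factory=GenParams)
    mn_specs: tuple[str, ...] = ("1_2", "1_4")
    duration_specs: tuple[str, ...] = ("2_2", "2_2_exp", "2_2_gamma")
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    predictive_m: int = 10_000
    render_trees: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gen_params"] = json.loads(self.gen_params.to_json())
        return json.dumps(d, indent=2)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def _write(path: Path, text: str, digests: dict) -> None:
    path.write_text(text, encoding="utf-8")
    digests[path.name] = _digest(text)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "data"
        if config.input_path is not None:
            dataset = read_tidy(config.input_path)
        else:
            dataset = simulate_dataset(config.gen_params, seed=config.seed)
        _write(out / "dataset.csv", write_tidy(dataset), digests)
        log.info("dataset: %d records, %d lineages", len(dataset), len(dataset.lineage_ids))

        stage = "validate"
        report = validate(dataset)
        _write(out / "validation.json", report.to_json(), digests)
        if not report.ok:
            log.warning("validation found %d violations", len(report.violations))

        stage = "trees"
        trees = build_trees(dataset)
        pct = abnormality_percentages(trees)
        _write(out / "abnormality_percentages.tsv", pct.to_csv(sep="\t", index=False), digests)

        stage = "fit"
        data = design_matrix(dataset)
        fits = {}
        for name in tuple(config.mn_specs) + tuple(config.duration_specs):
            log.info("fitting %s", name)
            res = LineageFateModel(name, data).fit(
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=config.seed,
            )
            fits[name] = res
            _write(out / f"summary_{name}.tsv", res.summary().to_csv(sep="\t"), digests)

        stage = "waic"
        for family, names in (("mn", config.mn_specs), ("duration", config.duration_specs)):
            if len(names) >= 1:
                table = rank_models([fits[n].waic() for n in names])
                _write(out / f"waic_{family}.tsv", table.to_csv(sep="\t", index=False), digests)
                _write(
                    out / f"waic_{family}.json",
                    table.to_json(orient="records", indent=2),
                    digests,
                )

        stage = "predict"
        predictions: dict = {}
        mn_name = config.mn_specs[-1] if config.mn_specs else None
        if mn_name:
            res = fits[mn_name]
            fc = res.mn_fold_change({"scf": 1}, {}, seed=config.seed)
            predictions["mn"] = {
                "model": mn_name,
                "average_prob_scf": fc["average_with"],
                "average_prob_baseline": fc["average_without"],
                "fold_change": fc["fold_change"],
            }
        dur_name = config.duration_specs[0] if config.duration_specs else None
        if dur_name:
            res = fits[dur_name]
            iqr_rows = []
            for cond in res.data.conditions:
                for mn in (0, 1):
                    samples = res.predictive_durations(
                        cond, mn, m=config.predictive_m, seed=config.seed + mn
                    )
                    q = duration_quartiles_iqr(samples)
                    iqr_rows.append(
                        {"cell_line": cond[0], "treatment": cond[1], "stage": cond[2], "mn": mn, **q}
                    )
            predictions["duration_iqr"] = {"model": dur_name, "rows": iqr_rows}
        _write(out / "predictions.json", json.dumps(predictions, indent=2), digests)

        stage = "pairs"
        pairs = find_matched_pairs(trees)
        pair_block: dict = {"n_pairs": len(pairs)}
        if pairs:
            comp = compare_pairs(pairs)
            test = chisq_2x2(comp["table"])
            pair_block.update(
                mn_plus_more=comp["mn_plus_more"],
                mn_minus_more=comp["mn_minus_more"],
                ties=comp["ties"],
                chisq=test,
                probability=event_probability(comp["mn_plus_more"], comp["n_pairs"]),
            )
            _write(out / "pairs.tsv", pair_table(pairs).to_csv(sep="\t", index=False), digests)
        _write(out / "pairs.json", json.dumps(pair_block, indent=2), digests)

        if config.render_trees:
            stage = "trees_render"
            render_gallery(trees, out / "trees")
    except Exception as exc:  # partial outputs stay on disk for debugging
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.to_json()),
        "seed": config.seed,
        "n_records": len(dataset),
        "n_lineages": len(dataset.lineage_ids),
        "artifact_digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
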