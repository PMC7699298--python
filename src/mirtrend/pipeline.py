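"""Pipeline configuration and the stage-chaining runner.

A YAML config names the inputs and parameters of any subset of the stages
(pool comparison, ddCt quantification, meta-analysis, trend screen,
enrichment); ``run_pipeline`` executes the configured stages in order,
writes one output table per stage plus a provenance JSON (seed, version,
parameters, inputs) that allows a bit-identical re-run, and aborts with the
stage name on the first error.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as mio
from .enrich import enrich_collection
from .meta import RandomEffectsMeta
from .qpcr import DeltaDeltaCtModel
from .pool import compare_groups
from .screen import TrendScreen

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("pool", "qpcr", "meta", "screen", "enrich")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage names to their parameter blocks; relative input
    paths are resolved against the config file's directory.
    """

    stages: dict
    seed: int = 0
    outdir: Path = Path("mirtrend_out")
    base_dir: Path = Path(".")

    _PATH_KEYS = {
        "pool": ("counts", "design"),
        "qpcr": ("ct",),
        "meta": ("studies",),
        "screen": ("expression", "design", "gene_list"),
        "enrich": ("gene_sets",),
    }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = {k: raw[k] for k in _STAGES if k in raw}
        cfg = cls(
            stages=stages,
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "mirtrend_out")),
            base_dir=path.parent,
        )
        cfg.validate()
        return cfg

    def resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
        for stage, block in self.stages.items():
            for key in self._PATH_KEYS.get(stage, ()):
                p = block.get(key)
                if p is not None and not self.resolve(p).exists():
                    raise FileNotFoundError(f"stage {stage!r}: input {key!r} not found: {p}")
        if "enrich" in self.stages and "screen" not in self.stages:
            raise ValueError("the enrich stage needs the screen stage to produce a ranking")


def _load_gene_list(path) -> list[str]:
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        coll = mio.read_gmt(path)
        out: list[str] = []
        for members in coll.sets.values():
            out.extend(m for m in members if m not in out)
        return out
    return [line.strip() for line in path.read_text().splitlines() if line.strip() and not line.startswith("#")]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a bundle of in-memory results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    provenance: dict = {"seed": config.seed, "stages": {}}

    if "pool" in config.stages:
        blk = config.stages["pool"]
        try:
            table = mio.read_count_table(config.resolve(blk["counts"]), config.resolve(blk["design"]))
            cmp_frames = []
            pairs = blk.get("comparisons") or [[blk["group_a"], blk["group_b"]]]
            for ga, gb in pairs:
                df = compare_groups(table, ga, gb, use_normalized=blk.get("use_normalized", True))
                cmp_frames.append(df.reset_index())
            import pandas as pd

            result = pd.concat(cmp_frames, ignore_index=True)
            mio.write_tsv(out / "pool_comparisons.tsv", result, params=blk, index=False)
            bundle["pool"] = result
            provenance["stages"]["pool"] = dict(blk)
        except Exception as exc:
            raise PipelineError("pool", exc) from exc

    if "qpcr" in config.stages:
        blk = config.stages["qpcr"]
        try:
            ct = mio.read_ct_table(config.resolve(blk["ct"]))
            res = DeltaDeltaCtModel(
                ct, blk["target"], blk["references"], blk["calibrator"]
            ).fit()
            mio.write_tsv(out / "relative_expression.tsv", res.summary(), params=blk)
            bundle["qpcr"] = res
            provenance["stages"]["qpcr"] = dict(blk)
        except Exception as exc:
            raise PipelineError("qpcr", exc) from exc

    if "meta" in config.stages:
        blk = config.stages["meta"]
        try:
            studies = mio.read_study_summaries(config.resolve(blk["studies"]))
            res = RandomEffectsMeta(studies, effect_scale=blk.get("effect_scale", "smd")).fit()
            mio.write_tsv(out / "meta_forest.tsv", res.forest_table(), params=blk, index=False)
            bundle["meta"] = res
            provenance["stages"]["meta"] = dict(blk)
        except Exception as exc:
            raise PipelineError("meta", exc) from exc

    screen_res = None
    if "screen" in config.stages:
        blk = config.stages["screen"]
        try:
            study = mio.read_expression(config.resolve(blk["expression"]), config.resolve(blk["design"]))
            gene_list = _load_gene_list(config.resolve(blk["gene_list"])) if blk.get("gene_list") else None
            model = TrendScreen(
                study,
                alpha=float(blk.get("alpha", 0.05)),
                n_perm=int(blk.get("n_perm", 10_000)),
                correction=blk.get("correction", "bh"),
                gene_list=gene_list,
            )
            screen_res = model.fit(seed=config.seed)
            mio.write_tsv(out / "trend_results.tsv", screen_res.table, params=blk)
            mio.write_json(out / "screen_summary.json", screen_res.counts)
            bundle["screen"] = screen_res
            provenance["stages"]["screen"] = dict(blk)
        except Exception as exc:
            raise PipelineError("screen", exc) from exc

    if "enrich" in config.stages:
        blk = config.stages["enrich"]
        try:
            collection = mio.read_gmt(config.resolve(blk["gene_sets"]))
            ranked, scores = screen_res.ranking()
            results = enrich_collection(
                ranked,
                scores,
                collection,
                n_perm=int(blk.get("n_perm", 10_000)),
                seed=config.seed,
                weight_exponent=float(blk.get("weight_exponent", 1.0)),
            )
            import pandas as pd

            df = pd.DataFrame(
                [
                    {
                        "set_name": r.set_name,
                        "es": r.es,
                        "empirical_p": r.empirical_p,
                        "leading_edge": ",".join(r.leading_edge),
                    }
                    for r in results
                ]
            )
            mio.write_tsv(out / "enrichment.tsv", df, params=blk, index=False)
            bundle["enrich"] = results
            provenance["stages"]["enrich"] = dict(blk)
        except Exception as exc:
            raise PipelineError("enrich", exc) from exc

    from . import __version__

    provenance["version"] = __version__
    mio.write_json(out / "provenance.json", provenance)
    bundle["provenance"] = provenance
    return bundle
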