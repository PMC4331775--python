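"""End-to-end orchestration: simulate -> preprocess -> DE -> classify -> enrich.

Every stage writes plain tab-delimited files into the output directory so
any stage can be re-run standalone on user data, the full configuration
is serialized alongside the outputs for provenance, and a machine-
readable summary (JSON) plus a text report close the run. Given a fixed
seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import diffexpr, enrich, preprocess, synth

__all__ = ["PipelineConfig", "RunResult", "run_pipeline", "make_report"]

log = logging.getLogger("dualsens")


@dataclass
class PipelineConfig:
    """Everything one run needs; fully serializable to YAML."""

    design: synth.StudyDesign = field(default_factory=synth.StudyDesign)
    synth_cfg: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    q_threshold: float = 0.2
    require_direction: bool = False
    go_min: int = enrich.DEFAULT_MIN_EXCL
    go_max: int = enrich.DEFAULT_MAX_EXCL
    alpha: float = enrich.DEFAULT_ALPHA
    adjust: str = "bh"
    use_probe_level: bool = True
    n_go_terms: int = 150
    plant_enrichment: bool = True
    out_dir: Path = Path("dualsens_run")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0, 1]")
        if self.go_min >= self.go_max:
            raise ValueError("go_min must be below go_max")
        self.out_dir = Path(self.out_dir)
        # one seed drives the whole run
        self.synth_cfg = dataclasses.replace(self.synth_cfg, seed=self.seed)

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["tissues"] = list(self.design.tissues)
        eff = self.synth_cfg.effects
        if eff is not None:
            d["synth_cfg"]["effects"] = {
                t: dataclasses.asdict(e) for t, e in eff.items()
            }
        d["out_dir"] = str(self.out_dir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            dd["tissues"] = tuple(dd.get("tissues", ("muscle", "prostate")))
            d["design"] = synth.StudyDesign(**dd)
        if "synth_cfg" in d:
            sc = dict(d["synth_cfg"])
            if sc.get("effects") is not None:
                sc["effects"] = {
                    t: synth.TissueEffects(**e) for t, e in sc["effects"].items()
                }
            d["synth_cfg"] = synth.SynthConfig(**sc)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunResult:
    """Everything the report needs, plus the JSON-ready summary."""

    config: PipelineConfig
    summary: dict
    calls: dict            # tissue -> calls DataFrame
    contrasts: dict        # tissue -> {comparison -> DataFrame}
    enrichment: dict       # tissue -> {category -> DataFrame}


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Run every stage, writing tab-delimited outputs under ``cfg.out_dir``.

    Raises with the failing stage's name attached so partial runs are
    diagnosable; outputs written before the failure stay on disk.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        _stage(stage)
        expr_true, truth = synth.generate_expression(cfg.design, cfg.synth_cfg)
        synth.write_truth(truth, out / "truth.tsv")
        if cfg.use_probe_level:
            probes = synth.generate_probe_level(expr_true, cfg.synth_cfg)
            synth.write_probe_level(
                probes, out / "probes.tsv", out / "samples.tsv"
            )
            stage = "preprocess"
            _stage(stage)
            expr = preprocess.rma(probes)
        else:
            expr = expr_true
        synth.write_expression(expr, out / "expression.tsv", out / "samples.tsv")

        contrasts: dict = {}
        calls: dict = {}
        venns: dict = {}
        for tissue in cfg.design.tissues:
            stage = f"diffexpr[{tissue}]"
            _stage(stage)
            res = diffexpr.run_all_comparisons(expr, tissue)
            for comp, table in res.items():
                table.to_csv(
                    out / f"de_{tissue}_{comp}.tsv", sep="\t", index_label="gene_id"
                )
            contrasts[tissue] = res

            stage = f"classify[{tissue}]"
            _stage(stage)
            tissue_calls = _classify.classify_sensitivity(
                res, cfg.q_threshold, cfg.require_direction
            )
            tissue_calls.to_csv(
                out / f"calls_{tissue}.tsv", sep="\t", index_label="gene_id"
            )
            calls[tissue] = tissue_calls
            venn = _classify.venn_partition(tissue_calls)
            venns[tissue] = venn
            log.info(
                "%s: androgen=%d follistatin=%d both=%d",
                tissue, venn.n_androgen, venn.n_follistatin, venn.n_both,
            )

        stage = "enrich"
        _stage(stage)
        planted = {}
        if cfg.plant_enrichment:
            for ti, tissue in enumerate(cfg.design.tissues):
                tt = truth[truth["tissue"] == tissue]
                androgen_true = tt.loc[tt["is_androgen_sensitive"], "gene"].tolist()
                take = androgen_true[: max(int(0.6 * len(androgen_true)), 0)]
                if len(take) >= 10:
                    planted[f"GO:{9000000 + ti:07d}"] = take
        dag, direct = synth.generate_ontology(
            cfg.n_go_terms, cfg.synth_cfg.n_genes, cfg.synth_cfg, planted=planted
        )
        synth.write_obo(dag, out / "ontology.obo")
        synth.write_annotations(direct, out / "annotations.tsv")
        ann = enrich.propagate(dag, direct)

        enrichment: dict = {}
        for tissue in cfg.design.tissues:
            enrichment[tissue] = {}
            tissue_calls = calls[tissue]
            for category, mask in (
                ("androgen", tissue_calls["androgen_sensitive"]),
                ("follistatin", tissue_calls["follistatin_sensitive"]),
                ("both", tissue_calls["androgen_sensitive"]
                         & tissue_calls["follistatin_sensitive"]),
            ):
                genes = set(tissue_calls.index[mask])
                if not genes:
                    log.info("%s/%s: empty selection, enrichment skipped",
                             tissue, category)
                    continue
                table = enrich.enrich(
                    genes, ann, dag,
                    min_excl=cfg.go_min, max_excl=cfg.go_max, adjust=cfg.adjust,
                )
                table.to_csv(
                    out / f"enrich_{tissue}_{category}.tsv", sep="\t", index=False
                )
                enrichment[tissue][category] = table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": cfg.seed,
        "q_threshold": cfg.q_threshold,
        "go_filter": {"min_excl": cfg.go_min, "max_excl": cfg.go_max},
        "alpha": cfg.alpha,
        "adjust": cfg.adjust,
        "n_genes": cfg.synth_cfg.n_genes,
        "replicates_per_group": cfg.design.replicates_per_group,
        "tissues": {},
    }
    for tissue in cfg.design.tissues:
        venn = venns[tissue]
        tsum = {
            "n_androgen": venn.n_androgen,
            "n_follistatin": venn.n_follistatin,
            "n_both": venn.n_both,
            "enrichment": {},
        }
        for category, table in enrichment[tissue].items():
            sig = table[table["p_adjusted"] < cfg.alpha]
            tsum["enrichment"][category] = {
                "n_terms_tested": int(len(table)),
                "n_significant": int(len(sig)),
                "top_term": None if table.empty else str(table.iloc[0]["term"]),
                "top_p_adjusted": None if table.empty
                else float(table.iloc[0]["p_adjusted"]),
            }
        summary["tissues"][tissue] = tsum

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    result = RunResult(cfg, summary, calls, contrasts, enrichment)
    (out / "report.txt").write_text(make_report(result))
    return result


def make_report(result: RunResult) -> str:
    """Plain-text run report: thresholds, Venn counts, per-category gene lists."""
    cfg = result.config
    lines = [
        "dualsens run report",
        "===================",
        f"seed: {cfg.seed}",
        f"q threshold: {cfg.q_threshold}",
        f"GO term filter: count in ({cfg.go_min}, {cfg.go_max}) exclusive",
        f"enrichment alpha (adjusted p): {cfg.alpha:.6g}",
        f"adjustment: {cfg.adjust}",
        "",
    ]
    for tissue, tsum in result.summary["tissues"].items():
        lines.append(f"[{tissue}]")
        lines.append(
            f"  androgen-sensitive: {tsum['n_androgen']}   "
            f"follistatin-sensitive: {tsum['n_follistatin']}   "
            f"both: {tsum['n_both']}"
        )
        calls = result.calls[tissue]
        q_cx = result.contrasts[tissue]["cx_vs_sham"]["q"]
        for category in ("uniquely_androgen", "uniquely_follistatin", "both"):
            genes = calls.index[calls["category"] == category]
            ordered = q_cx.reindex(genes).sort_values()
            shown = ", ".join(ordered.index[:15])
            more = "" if len(ordered) <= 15 else f" … (+{len(ordered) - 15} more)"
            lines.append(f"  {category} ({len(ordered)}): {shown}{more}")
        for category, esum in tsum["enrichment"].items():
            if esum["top_term"] is None:
                top = "none (no terms tested)"
            else:
                top = f"{esum['top_term']} (adj p = {esum['top_p_adjusted']:.3g})"
            lines.append(
                f"  enrichment[{category}]: {esum['n_significant']} of "
                f"{esum['n_terms_tested']} terms significant; top {top}"
            )
        lines.append("")
    return "\n".join(lines)
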