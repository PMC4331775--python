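"""Synthetic microarray study generator with known ground truth.

Emulates a two-tissue, four-condition castration study: sham-operated
controls, castrated (cx), castrated + testosterone (cx_T) and castrated
+ recombinant follistatin (cx_F), with replicated arrays per group.
Planted per-gene condition effects define which genes are androgen
and/or follistatin sensitive; the generator returns that truth alongside
the data so recovery can be measured exactly.

The default effect structure mirrors the biology the pipeline is built
to detect: in muscle, testosterone- and follistatin-responsive genes
overlap heavily (~46% of androgen-sensitive genes also follistatin
sensitive), while in prostate follistatin effects are nearly absent.

Everything is driven by one global seed through numpy's SeedSequence
spawning: child 0 -> expression, child 1 -> probe level, child 2 ->
ontology/annotations. Identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import BIOLOGICAL_PROCESS, GoDag
from .preprocess import ExpressionMatrix, ProbeLevelData

__all__ = [
    "CONDITIONS",
    "StudyDesign",
    "TissueEffects",
    "SynthConfig",
    "DEFAULT_TISSUE_EFFECTS",
    "generate_expression",
    "generate_probe_level",
    "generate_ontology",
    "write_expression",
    "read_expression",
    "write_probe_level",
    "read_probe_level",
    "write_truth",
    "write_obo",
    "write_annotations",
    "write_gaf",
]

CONDITIONS = ("sham", "cx", "cx_T", "cx_F")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Tissues x conditions x replicates layout of the simulated study."""

    tissues: tuple = ("muscle", "prostate")
    replicates_per_group: int = 4

    def __post_init__(self) -> None:
        if len(set(self.tissues)) != len(self.tissues) or not self.tissues:
            raise ConfigurationError("tissue labels must be unique and non-empty")
        if self.replicates_per_group < 2:
            raise ConfigurationError("need at least 2 replicates per group")

    @property
    def conditions(self) -> tuple:
        return CONDITIONS


@dataclass(frozen=True)
class TissueEffects:
    """Planted sensitive-gene fractions for one tissue.

    ``frac_androgen`` / ``frac_follistatin`` are total fractions of genes
    carrying each flag; ``overlap`` is the fraction of androgen-sensitive
    genes that are also follistatin sensitive (n_both = overlap * n_androgen,
    bounded by the follistatin count). ``frac_cx_only`` genes respond to
    castration but to neither treatment — realistic decoys for the
    dual-contrast rule.
    """

    frac_androgen: float = 0.04
    frac_follistatin: float = 0.04
    overlap: float = 0.46
    frac_cx_only: float = 0.02

    def __post_init__(self) -> None:
        for name in ("frac_androgen", "frac_follistatin", "overlap", "frac_cx_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


# Fractions scaled from the observed tissue contrast: in muscle both
# hormones regulate overlapping programs; in prostate follistatin is inert.
DEFAULT_TISSUE_EFFECTS: dict = {
    "muscle": TissueEffects(
        frac_androgen=0.043, frac_follistatin=0.039, overlap=0.46, frac_cx_only=0.02
    ),
    "prostate": TissueEffects(
        frac_androgen=0.030, frac_follistatin=0.0005, overlap=0.012, frac_cx_only=0.02
    ),
}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; the seed fixes every output bit-for-bit.

    Effect magnitudes |delta| are Uniform[effect_low, effect_high] log2
    units with random sign; per-gene residual sds follow a scaled
    inverse-chi-square prior (sigma0 = 0.25 log2 units, d0 = 4), the same
    family the moderated-t machinery assumes.
    """

    n_genes: int = 2000
    effects: Mapping[str, TissueEffects] | None = None
    effect_low: float = 0.5
    effect_high: float = 2.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    sigma_prior_df: float = 4.0
    sigma_prior_scale: float = 0.25   # sigma0, log2 units
    n_probes: int = 11
    probe_affinity_sd: float = 0.4
    bg_mean: float = 40.0
    bg_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_probes < 1:
            raise ConfigurationError("probe count must be >= 1")
        if self.effect_low < 0 or self.effect_high < self.effect_low:
            raise ConfigurationError("need 0 <= effect_low <= effect_high")
        if self.probe_affinity_sd < 0 or self.bg_sd < 0:
            raise ConfigurationError("noise sds must be non-negative")
        if self.sigma_prior_scale < 0:
            raise ConfigurationError("sigma prior scale must be non-negative")

    def tissue_effects(self, tissue: str) -> TissueEffects:
        if self.effects is not None and tissue in self.effects:
            return self.effects[tissue]
        return DEFAULT_TISSUE_EFFECTS.get(tissue, TissueEffects())

    def _rng(self, stream: int) -> np.random.Generator:
        # stream 0: expression, 1: probe level, 2: ontology
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])


def _gene_ids(n: int) -> list:
    return [f"gene{i:05d}" for i in range(n)]


def _draw_effects(rng: np.random.Generator, size: int, cfg: SynthConfig) -> np.ndarray:
    mag = rng.uniform(cfg.effect_low, cfg.effect_high, size)
    sign = rng.choice([-1.0, 1.0], size)
    return mag * sign


def generate_expression(
    design: StudyDesign, cfg: SynthConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the log2 probeset x sample matrix plus its effect truth.

    Condition means per gene: sham = baseline; cx = baseline + delta_cx;
    cx_T = cx + delta_T; cx_F = cx + delta_F, with delta_T = -delta_cx for
    androgen-sensitive genes (restoration) and delta_F = -delta_cx for
    follistatin-sensitive genes. Gaussian noise N(0, sigma_g^2) is added
    per measurement.

    The truth table has one row per gene x tissue with the deltas, the
    residual sd, and flags that are by construction the indicator of the
    corresponding deltas being nonzero.
    """
    rng = cfg._rng(0)
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_genes
    reps = design.replicates_per_group

    sample_rows = []
    value_blocks = []
    truth_rows = []
    for tissue in design.tissues:
        eff = cfg.tissue_effects(tissue)
        n_a = int(round(eff.frac_androgen * n))
        n_f = int(round(eff.frac_follistatin * n))
        n_both = min(int(round(eff.overlap * n_a)), n_a, n_f)
        n_cx_only = int(round(eff.frac_cx_only * n))
        if n_a + (n_f - n_both) + n_cx_only > n:
            raise ConfigurationError("sensitive fractions exceed the gene count")

        perm = rng.permutation(n)
        androgen_idx = perm[:n_a]
        both_idx = androgen_idx[:n_both]
        foll_only_idx = perm[n_a : n_a + (n_f - n_both)]
        cx_only_idx = perm[n_a + (n_f - n_both) : n_a + (n_f - n_both) + n_cx_only]
        follistatin_idx = np.concatenate([both_idx, foll_only_idx])

        delta_cx = np.zeros(n)
        delta_t = np.zeros(n)
        delta_f = np.zeros(n)
        cx_responders = np.concatenate([androgen_idx, foll_only_idx, cx_only_idx])
        delta_cx[cx_responders] = _draw_effects(rng, cx_responders.size, cfg)
        delta_t[androgen_idx] = -delta_cx[androgen_idx]
        delta_f[follistatin_idx] = -delta_cx[follistatin_idx]

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
        if cfg.sigma_prior_scale == 0:
            sigma = np.zeros(n)
        else:
            d0, s0 = cfg.sigma_prior_df, cfg.sigma_prior_scale
            sigma = np.sqrt(d0 * s0**2 / rng.chisquare(d0, n))

        cond_means = {
            "sham": baseline,
            "cx": baseline + delta_cx,
            "cx_T": baseline + delta_cx + delta_t,
            "cx_F": baseline + delta_cx + delta_f,
        }
        for cond in CONDITIONS:
            noise = rng.normal(0.0, 1.0, (n, reps)) * sigma[:, None]
            block = cond_means[cond][:, None] + noise
            for r in range(reps):
                sample_rows.append((f"{tissue}_{cond}_r{r + 1}", tissue, cond, r + 1))
            value_blocks.append(block)

        is_androgen = (delta_cx != 0) & (delta_t != 0)
        is_follistatin = (delta_cx != 0) & (delta_f != 0)
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "tissue": tissue,
                    "delta_cx": delta_cx,
                    "delta_T": delta_t,
                    "delta_F": delta_f,
                    "sigma": sigma,
                    "is_androgen_sensitive": is_androgen,
                    "is_follistatin_sensitive": is_follistatin,
                }
            )
        )

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "condition", "replicate"]
    ).set_index("sample_id")
    values = pd.DataFrame(
        np.concatenate(value_blocks, axis=1), index=genes, columns=samples.index
    )
    truth = pd.concat(truth_rows, ignore_index=True)
    return ExpressionMatrix(values, samples), truth


def generate_probe_level(expr: ExpressionMatrix, cfg: SynthConfig) -> ProbeLevelData:
    """Explode expression values into linear-scale probe intensities.

    Each probeset gets ``cfg.n_probes`` probes with fixed log2 affinities
    (shared across samples); observed intensity is
    2^(expression + affinity) + Normal(bg_mean, bg_sd) background,
    floored just above zero so the linear scale stays valid.
    """
    rng = cfg._rng(1)
    genes = list(expr.values.index)
    n_probes = cfg.n_probes
    affinities = rng.normal(0.0, cfg.probe_affinity_sd, (len(genes), n_probes))

    probe_ids = [f"{g}:p{j:02d}" for g in genes for j in range(n_probes)]
    probesets = pd.Series(
        [g for g in genes for _ in range(n_probes)], index=probe_ids, name="probeset_id"
    )
    expr_vals = expr.values.to_numpy(dtype=float)
    signal = 2.0 ** (
        np.repeat(expr_vals, n_probes, axis=0) + affinities.reshape(-1)[:, None]
    )
    if cfg.bg_sd > 0 or cfg.bg_mean != 0:
        background = rng.normal(cfg.bg_mean, cfg.bg_sd, signal.shape)
    else:
        background = 0.0
    intensities = np.maximum(signal + background, 2.0**-10)
    frame = pd.DataFrame(intensities, index=probe_ids, columns=expr.values.columns)
    return ProbeLevelData(frame, probesets, expr.samples)


def generate_ontology(
    n_terms: int,
    n_genes: int,
    cfg: SynthConfig,
    mean_direct: float = 1.5,
    frac_unannotated: float = 0.1,
    planted: Mapping[str, Iterable] | None = None,
) -> tuple[GoDag, dict]:
    """Random rooted is_a DAG plus sparse direct gene annotations.

    Term 0 is the biological_process root; each later term attaches to one
    random earlier term, with a 30% chance of a second parent — the DAG is
    acyclic by construction and gains specificity away from the root.
    Each annotated gene gets 1 + Poisson(mean_direct - 1) direct non-root
    terms; ``frac_unannotated`` genes carry no annotation at all.

    ``planted`` maps extra term ids to the exact gene sets to annotate;
    each planted term is added as a fresh leaf under the root, so its
    propagated count equals the planted set size.
    """
    if n_terms < 2:
        raise ConfigurationError("need at least 2 ontology terms")
    rng = cfg._rng(2)
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    g = nx.DiGraph()
    names = {term_ids[0]: BIOLOGICAL_PROCESS}
    g.add_node(term_ids[0])
    for i in range(1, n_terms):
        g.add_node(term_ids[i])
        names[term_ids[i]] = f"synthetic process {i}"
        parent = int(rng.integers(0, i))
        g.add_edge(term_ids[i], term_ids[parent])
        if i >= 2 and rng.random() < 0.3:
            second = int(rng.integers(0, i))
            if second != parent:
                g.add_edge(term_ids[i], term_ids[second])

    genes = _gene_ids(n_genes)
    annotated = rng.random(n_genes) >= frac_unannotated
    direct: dict = {}
    non_root = term_ids[1:]
    for gi, gene in enumerate(genes):
        if not annotated[gi]:
            continue
        n_ann = 1 + int(rng.poisson(max(mean_direct - 1.0, 0.0)))
        n_ann = min(n_ann, len(non_root))
        picks = rng.choice(len(non_root), size=n_ann, replace=False)
        direct[gene] = frozenset(non_root[i] for i in picks)

    if planted:
        for term, plant_genes in planted.items():
            if term in g:
                raise ConfigurationError(f"planted term {term!r} already exists")
            g.add_node(term)
            g.add_edge(term, term_ids[0])
            names[term] = f"planted process {term}"
            for gene in plant_genes:
                direct[gene] = frozenset(direct.get(gene, frozenset()) | {term})
    return GoDag(g, term_ids[0], names), direct


# ---------------------------------------------------------------------------
# text serialization (tab-delimited tables, minimal OBO, GAF 2.2)
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, values_path, samples_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    expr.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_expression(values_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values, samples)


def write_probe_level(data: ProbeLevelData, probes_path, samples_path) -> None:
    out = data.intensities.copy()
    out.insert(0, "probeset_id", data.probesets)
    out.to_csv(probes_path, sep="\t", index_label="probe_id")
    data.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_probe_level(probes_path, samples_path) -> ProbeLevelData:
    table = pd.read_csv(probes_path, sep="\t", index_col="probe_id")
    probesets = table.pop("probeset_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ProbeLevelData(table, probesets, samples)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_obo(dag: GoDag, path) -> None:
    """Emit the DAG as minimal OBO 1.2 term stanzas (id, name, namespace, is_a)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name(term)}")
        lines.append(f"namespace: {BIOLOGICAL_PROCESS}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {dag.name(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(direct: Mapping, path) -> None:
    """Two-column gene<TAB>term table of direct annotations."""
    with open(path, "w") as fh:
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_gaf(direct: Mapping, path, taxon: str = "taxon:10090") -> None:
    """GAF 2.2 emitter (17 columns, biological_process aspect, IEA evidence)."""
    today = date.today().strftime("%Y%m%d")
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                row = [
                    "SYNTH", gene, gene, "involved_in", term, "SYNTH:0000001",
                    "IEA", "", "P", gene, "", "protein", taxon, today, "SYNTH",
                    "", "",
                ]
                fh.write("\t".join(row) + "\n")
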