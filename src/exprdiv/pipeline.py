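"""End-to-end analysis: transforms -> exponent scan -> clustering ->
null construction -> conserved calls -> entropy contrast.

:func:`analyze` ties the stages together on a pair of expression
matrices (loaded from TSV or simulated), runs every configured measure,
and writes all artifacts plus a single JSON run summary that records the
software version, the full configuration, every seed, and the numerical
conventions in force -- the provenance needed to audit choices (linkage,
quantile rule, tie policies) that materially affect the results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from ._version import __version__
from .cluster import average_link_cluster, homologous_pairing_score, sample_distance_matrix
from .distances import pairwise_distances
from .divergence import (
    build_null,
    call_conserved,
    contrast_called_sets,
    upper_quartile_entropy_genes,
)
from .errors import ConfigError, ExprDivError
from . import io as edio
from .selection import DEFAULT_LAMBDA_GRID, scan_ga_exponents
from .simulate import SyntheticConfig, generate_paired_expression, generate_random_pairs
from .transforms import gene_entropy, to_binary, to_relative

__all__ = ["RunConfig", "DEFAULT_MEASURES", "analyze", "simulate_to_files"]

log = logging.getLogger("exprdiv")

#: The four measures of the comparative analysis; GA enters with the
#: max-overlap exponent selected by the moment criterion.
DEFAULT_MEASURES = (
    ("correlation", {}),
    ("euclidean", {}),
    ("binary_correlation", {}),
    ("ga", {"lam": math.inf}),
)

#: Numerical conventions recorded in every run summary.
CONVENTIONS = {
    "binarization": "x_B = 1 iff x >= row mean (ties to 1)",
    "clustering_input": "relative expression for euclidean/correlation panels",
    "linkage": "average-link (unweighted cross-pair mean), lexicographic tie-break",
    "null_quantile": "nearest-rank lower quantile, ceil(alpha*N)-th smallest",
    "call_boundary": "distance <= threshold is called (inclusive)",
    "moment_convention": "biased (/N) central moments; kurtosis reported as excess",
    "upper_quartile": "top ceil(N/4) genes by entropy, ties by ascending gene id",
    "random_pairing": "uniform permutation, rejected until fixed-point free",
    "entropy_profile_species": "species 1",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``synthetic`` is set (the data are simulated) or all three
    input paths are set.  ``seed`` drives the random re-pairing used to
    build the null.
    """

    synthetic: SyntheticConfig | None = None
    species1_path: str | None = None
    species2_path: str | None = None
    orthologs_path: str | None = None
    species_names: tuple[str, str] = ("species1", "species2")
    measures: tuple = DEFAULT_MEASURES
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    alpha: float = 0.01
    seed: int = 0
    outdir: str = "exprdiv_run"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie strictly in (0, 1)")
        paths = (self.species1_path, self.species2_path, self.orthologs_path)
        if self.synthetic is None:
            if any(p is None for p in paths):
                raise ConfigError(
                    "either a synthetic config or all three input paths are required"
                )
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        elif any(p is not None for p in paths):
            raise ConfigError("give either synthetic config or input paths, not both")


def _measure_tag(measure: str, params: dict) -> str:
    if measure == "ga":
        lam = params.get("lam")
        tag = {math.inf: "inf", -math.inf: "neg_inf"}.get(lam, str(lam))
        return f"ga_lam_{tag}"
    return measure


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        mat1, mat2, pairs, truth = generate_paired_expression(cfg.synthetic)
        return mat1, mat2, pairs, truth
    mat1 = edio.read_expression(cfg.species1_path, species=cfg.species_names[0])
    mat2 = edio.read_expression(cfg.species2_path, species=cfg.species_names[1])
    pairs = edio.read_orthologs(cfg.orthologs_path)
    return mat1, mat2, pairs, None


def simulate_to_files(config: SyntheticConfig, outdir) -> dict:
    """Simulate a paired dataset and write the five standard files.

    Writes the two species expression TSVs, the ortholog map, the ground
    truth table, and a metadata JSON recording the seed and config.
    Returns the file manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat1, mat2, pairs, truth = generate_paired_expression(config)
    files = {
        "species1": outdir / f"expression_{config.species_names[0]}.tsv",
        "species2": outdir / f"expression_{config.species_names[1]}.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "metadata": outdir / "simulation.json",
    }
    edio.write_expression(mat1, files["species1"])
    edio.write_expression(mat2, files["species2"])
    edio.write_orthologs(pairs, files["orthologs"], columns=config.species_names)
    edio.write_ground_truth(truth, files["ground_truth"])
    edio.write_json(
        {
            "seed": config.seed,
            "config": config.__dict__,
            "version": __version__,
            "files": {k: str(v) for k, v in files.items()},
        },
        files["metadata"],
    )
    log.info("simulated %d genes x %d tissues (seed=%d) into %s",
             config.n_genes, config.n_tissues, config.seed, outdir)
    return {k: str(v) for k, v in files.items()}


def analyze(cfg: RunConfig) -> dict:
    """Run the full comparative analysis; returns the run summary dict.

    Stages: per-gene transforms; GA exponent scan (moment criterion);
    cross-species tissue clustering under every measure (Newick tree +
    homologous-pairing score); random-pair null and conserved-pair calls
    per measure; upper-entropy-quartile selection; Euclidean-vs-
    correlation contrast of called sets.  All artifacts are written under
    ``cfg.outdir``; the summary JSON indexes them.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    summary: dict = {
        "version": __version__,
        "conventions": dict(CONVENTIONS),
        "alpha": cfg.alpha,
        "seed": cfg.seed,
        "outputs": {},
    }
    try:
        mat1, mat2, pairs, truth = _load_inputs(cfg)
        summary["n_orthologs"] = len(pairs)
        summary["n_tissues"] = int(mat1.n_tissues)
        if cfg.synthetic is not None:
            summary["synthetic_config"] = dict(cfg.synthetic.__dict__)
        else:
            summary["inputs"] = {
                "species1": cfg.species1_path,
                "species2": cfg.species2_path,
                "orthologs": cfg.orthologs_path,
            }

        stage = "transforms"
        rel1, rel2 = to_relative(mat1), to_relative(mat2)
        bin1, bin2 = to_binary(mat1), to_binary(mat2)
        entropy = gene_entropy(mat1)

        stage = "lambda-scan"
        scan = scan_ga_exponents(bin1, bin2, pairs, cfg.lambda_grid)
        scan_rows = [
            {
                "label": s.label,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "skewness": s.skewness,
                "kurtosis": s.kurtosis,
            }
            for s in scan.summaries
        ]
        summary["lambda_scan"] = {"rows": scan_rows, "selection": scan.selection}
        scan_path = outdir / "lambda_scan.tsv"
        with open(scan_path, "w", encoding="utf-8") as fh:
            fh.write("label\tn\tmean\tsd\tskewness\tkurtosis\n")
            for row in scan_rows:
                fh.write(
                    "\t".join(str(row[k]) for k in ("label", "n", "mean", "sd", "skewness", "kurtosis"))
                    + "\n"
                )
        summary["outputs"]["lambda_scan"] = str(scan_path)

        stage = "random-pairs"
        random_pairs = generate_random_pairs(pairs, seed=cfg.seed)

        summary["measures"] = {}
        transformed = {
            "euclidean": (rel1, rel2),
            "correlation": (rel1, rel2),
            "binary_correlation": (bin1, bin2),
            "ga": (bin1, bin2),
        }
        reports = {}
        for measure, params in cfg.measures:
            tag = _measure_tag(measure, params)

            stage = f"clustering[{tag}]"
            sdm = sample_distance_matrix(mat1, mat2, pairs, measure, params)
            tree = average_link_cluster(sdm)
            score = homologous_pairing_score(tree)
            tree_path = outdir / f"tree_{tag}.nwk"
            edio.write_newick(tree, tree_path)

            stage = f"null-and-calls[{tag}]"
            ta, tb = transformed[measure]
            orth_d = pairwise_distances(ta, tb, pairs, measure, params)
            rand_d = pairwise_distances(ta, tb, random_pairs, measure, params)
            null = build_null(rand_d, cfg.alpha)
            report = call_conserved(orth_d, null, mat1, mat2)
            reports[measure] = report

            dist_path = outdir / f"distances_{tag}.tsv"
            edio.write_distances(orth_d, dist_path, outdir / f"excluded_{tag}.tsv")
            calls_path = outdir / f"conserved_{tag}.tsv"
            if report.expression_by_species is not None:
                frame = report.expression_by_species.copy()
                frame.insert(0, "distance", report.called_values)
                frame.to_csv(calls_path, sep="\t")
            summary["measures"][tag] = {
                "pairing_score": score,
                "max_score": int(mat1.n_tissues),
                "threshold": null.threshold,
                "n_tested": report.n_tested,
                "n_excluded_ortholog": orth_d.n_excluded,
                "n_excluded_random": rand_d.n_excluded,
                "n_called": report.n_called,
                "called_fraction": report.called_fraction,
            }
            summary["outputs"][f"tree_{tag}"] = str(tree_path)
            summary["outputs"][f"distances_{tag}"] = str(dist_path)
            summary["outputs"][f"conserved_{tag}"] = str(calls_path)
            log.info("%s: pairing score %d/%d, %d/%d pairs called conserved",
                     tag, score, mat1.n_tissues, report.n_called, report.n_tested)

        stage = "entropy-quartile"
        top_genes = upper_quartile_entropy_genes(entropy)
        genes_path = outdir / "upper_quartile_entropy_genes.txt"
        genes_path.write_text("\n".join(top_genes) + "\n", encoding="utf-8")
        summary["entropy"] = {
            "n_genes": int(len(entropy)),
            "n_upper_quartile": len(top_genes),
        }
        summary["outputs"]["upper_quartile_entropy_genes"] = str(genes_path)

        stage = "contrast"
        if "euclidean" in reports and "correlation" in reports:
            contrast = contrast_called_sets(
                reports["euclidean"], reports["correlation"], mat1, mat2
            )
            summary["contrast_euclidean_vs_correlation"] = {
                "n_called": list(contrast.n_called),
                "median_mean_expression": list(contrast.medians),
                "median_difference": contrast.median_difference,
                "mannwhitney_u": contrast.mannwhitney_u,
                "empty_set": contrast.empty_set,
            }
    except ExprDivError as exc:
        summary["failed_stage"] = stage
        summary["partial"] = True
        edio.write_json(summary, outdir / "run_summary.json")
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["partial"] = True
        edio.write_json(summary, outdir / "run_summary.json")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    summary_path = outdir / "run_summary.json"
    edio.write_json(summary, summary_path)
    summary["outputs"]["run_summary"] = str(summary_path)
    return summary
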