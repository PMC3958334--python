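"""End-to-end pipeline driver.

Runs simulate (or load) -> plate normalization + QC -> replicate
aggregation -> hit calling with promoter filtering -> epistasis-interval
assignment + census -> specificity scoring -> functional-profile
clustering -> (optional) qPCR expression calls, writing every stage output
as TSV plus a run manifest.  All outputs are deterministic for a fixed
seed: rerunning with an identical config and seed reproduces byte-
identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .epistasis import EPISTASIS_ASSAYS, EpistasisClassifier, interval_census
from .expression import ExpressionCaller
from .hits import HitCaller
from .io import read_well_table, sha256_digest, write_table
from .normalize import PlateNormalizer, aggregate_replicates
from .simulate import ALL_ASSAYS, JNK_ASSAYS, REPORTER_ASSAYS, SimConfig, generate_screen, write_screen
from .specificity import ProfileClusterer, SpecificityScorer

log = logging.getLogger(__name__)

PRIMARY_ASSAY = EPISTASIS_ASSAYS[0]  # the RAS^V12-driven pMAPK screen


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sim_config(config: dict, seed: int | None) -> SimConfig:
    params = dict(config.get("simulate", {}))
    if seed is not None:
        params["seed"] = seed
    return SimConfig(**params)


def gene_value_matrix(aggregated: pd.DataFrame, wide_on: str = "assay") -> pd.DataFrame:
    """Pivot aggregated (reagent, assay, value) rows to a genes x assays table."""
    return aggregated.pivot(index="reagent_id", columns=wide_on, values="value")


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run every stage and write outputs under ``out_dir``.

    Parameters
    ----------
    config : pipeline configuration mapping; keys ``simulate`` (SimConfig
        fields) or ``inputs: {wells: path}``, plus optional ``hits``,
        ``epistasis``, ``specificity``, ``expression`` parameter blocks
        and ``inputs: {qpcr: path}`` for the expression stage.
    out_dir : output directory (created).
    seed : overrides ``simulate.seed`` when given.

    Returns
    -------
    The run manifest (also written as ``manifest.yaml``): config
    snapshot, seed, tool version, stage output paths with SHA-256
    digests.
    """
    out = Path(out_dir)
    inputs = config.get("inputs", {})
    simulate_mode = "wells" not in inputs

    # resolve inputs up front so a bad path fails before any output exists
    for key, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"input {key!r} not found: {path}")
    out.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, str] = {}
    truth = None
    if simulate_mode:
        cfg = _sim_config(config, seed)
        wells, truth = generate_screen(cfg)
        outputs.update(write_screen(wells, truth, cfg, out))
        used_seed = cfg.seed
    else:
        wells = read_well_table(inputs["wells"])
        used_seed = seed

    # --- normalization + QC ---------------------------------------------
    try:
        normalizer = PlateNormalizer(**config.get("normalize", {})).fit(wells)
        normalized = normalizer.transform(wells)
        qc = normalizer.qc(normalized)
    except ValueError as err:
        raise PipelineError("normalize", str(err)) from err
    write_table(normalized.drop(columns=["cells"], errors="ignore"), out / "normalized.tsv")
    write_table(qc, out / "qc.tsv")
    outputs["normalized"] = str(out / "normalized.tsv")
    outputs["qc"] = str(out / "qc.tsv")

    samples = normalized[normalized["role"] == "sample"]
    aggregated = aggregate_replicates(samples)
    write_table(aggregated, out / "aggregated.tsv")
    outputs["aggregated"] = str(out / "aggregated.tsv")
    matrix = gene_value_matrix(aggregated)

    # --- hit calling -----------------------------------------------------
    has_replicate = "replicate" in samples.columns and samples["replicate"].nunique() > 1
    per_rep = (
        samples.groupby(["reagent_id", "assay", "replicate"])["value"].mean().reset_index()
        if has_replicate
        else None
    )
    hit_input = pd.DataFrame({"reagent_id": matrix.index})
    if has_replicate:
        primary = per_rep[per_rep["assay"] == PRIMARY_ASSAY]
        rep_ids = sorted(primary["replicate"].unique())
        wide = primary.pivot(index="reagent_id", columns="replicate", values="value")
        hit_input["value_primary"] = wide[rep_ids[0]].reindex(matrix.index).to_numpy()
        hit_input["value_confirmation"] = wide[rep_ids[1]].reindex(matrix.index).to_numpy()
    else:
        hit_input["value_primary"] = matrix[PRIMARY_ASSAY].to_numpy()
    for assay in REPORTER_ASSAYS:
        if assay in matrix.columns:
            hit_input[f"reporter_{assay}"] = matrix[assay].to_numpy()
    hit_params = dict(config.get("hits", {}))
    hit_params.setdefault("require_confirmation", has_replicate)
    try:
        caller = HitCaller(**hit_params).fit(hit_input)
        hit_table = caller.call(hit_input)
    except ValueError as err:
        raise PipelineError("call-hits", str(err)) from err
    write_table(hit_table, out / "hits.tsv")
    outputs["hits"] = str(out / "hits.tsv")
    validated = hit_table.loc[hit_table["validated"], "reagent_id"]

    # --- epistasis -------------------------------------------------------
    profile_genes = matrix.loc[matrix.index.isin(validated), list(EPISTASIS_ASSAYS)]
    clf = EpistasisClassifier(**config.get("epistasis", {}))
    if len(profile_genes):
        calls = clf.fit(profile_genes).classify(profile_genes)
        calls = calls.rename_axis("gene").reset_index()
    else:
        calls = pd.DataFrame(
            columns=["gene", "r_ras_raf", "r_raf_mek", "r_mek_mapk",
                     "interval", "sign", "confidence", "status"]
        )
    write_table(calls, out / "epistasis_calls.tsv")
    outputs["epistasis_calls"] = str(out / "epistasis_calls.tsv")
    census = interval_census(calls.set_index("gene")) if len(calls) else interval_census(calls)
    write_table(census, out / "census.tsv")
    outputs["census"] = str(out / "census.tsv")

    # --- specificity -----------------------------------------------------
    spec_input = pd.DataFrame(
        {
            "gene": matrix.index,
            "pmapk_effect": matrix[PRIMARY_ASSAY].to_numpy(),
            "jnk_rac1": matrix.get(JNK_ASSAYS[0]),
            "jnk_pgn": matrix.get(JNK_ASSAYS[1]),
            "pmet_gfp_effect": matrix.get(REPORTER_ASSAYS[0]),
        }
    )
    spec_input = spec_input[spec_input["gene"].isin(validated)].reset_index(drop=True)
    if len(spec_input):
        scorer = SpecificityScorer(**config.get("specificity", {})).fit(spec_input)
        spec_report = scorer.transform(spec_input)
    else:
        spec_report = pd.DataFrame(columns=["gene", "final_score", "group"])
    write_table(spec_report, out / "specificity.tsv")
    outputs["specificity"] = str(out / "specificity.tsv")

    # --- clustering ------------------------------------------------------
    cluster_profiles_df = matrix.loc[matrix.index.isin(validated), list(ALL_ASSAYS)]
    cluster_profiles_df = cluster_profiles_df[
        (cluster_profiles_df.notna().all(axis=1))
        & (cluster_profiles_df.abs().sum(axis=1) > 0)
    ]
    if len(cluster_profiles_df) >= 2:
        tree = ProfileClusterer().fit(cluster_profiles_df)
        newick = tree.to_newick()
    else:
        newick = ";"
        log.warning("clustering skipped: fewer than 2 clusterable validated hits")
    (out / "cluster.nwk").write_text(newick + "\n")
    outputs["cluster"] = str(out / "cluster.nwk")

    # --- expression (optional input) -------------------------------------
    if "qpcr" in inputs:
        qpcr = pd.read_csv(inputs["qpcr"], sep="\t")
        try:
            exp = ExpressionCaller(**config.get("expression", {})).fit()
            exp_calls = exp.call_table(qpcr)
        except ValueError as err:
            raise PipelineError("expression", str(err)) from err
        write_table(exp_calls, out / "expression_calls.tsv")
        outputs["expression_calls"] = str(out / "expression_calls.tsv")

    # --- summary + manifest ----------------------------------------------
    summary = pd.DataFrame(
        {
            "quantity": [
                "n_wells",
                "n_genes",
                "n_hits",
                "n_validated",
                "n_assigned",
                "n_ambiguous",
                "n_unassigned",
            ],
            "value": [
                len(wells),
                matrix.shape[0],
                int(hit_table["is_hit"].sum()),
                int(hit_table["validated"].sum()),
                int((calls["status"] == "assigned").sum()) if len(calls) else 0,
                int((calls["status"] == "ambiguous").sum()) if len(calls) else 0,
                int((calls["status"] == "unassigned").sum()) if len(calls) else 0,
            ],
        }
    )
    write_table(summary, out / "summary.tsv")
    outputs["summary"] = str(out / "summary.tsv")

    manifest = {
        "tool": "mapkscreen",
        "version": __version__,
        "seed": used_seed,
        "config": _jsonable(config),
        "inputs": {k: {"path": str(v), "sha256": sha256_digest(v)} for k, v in inputs.items()},
        "outputs": {
            k: {"path": str(Path(v).name), "sha256": sha256_digest(v)}
            for k, v in sorted(outputs.items())
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
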