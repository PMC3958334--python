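"""Ground-truth evaluation of the full screen analysis chain.

Runs simulate -> normalize -> aggregate -> hit calling (with promoter
filtering) -> epistasis classification, then joins the calls back to the
generator's ground truth.  Used by the recovery benchmarks: a planted
regulator is recovered when it survives hit calling and its reported
interval and regulator sign match the truth; a neutral (pure-noise) gene
is correctly silent when it either never becomes a validated hit or is
left unassigned/ambiguous by the classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epistasis import EPISTASIS_ASSAYS, INTERVALS, classify_profiles
from .hits import HitCaller
from .normalize import PlateNormalizer, aggregate_replicates
from .simulate import REPORTER_ASSAYS, SimConfig, generate_screen


def evaluate_screen(cfg: SimConfig, hit_params: dict | None = None) -> pd.DataFrame:
    """Full-chain evaluation of one simulated screen.

    Returns one row per gene: ground-truth class/sign, the validated-hit
    flag, and (for validated genes) the epistasis call columns.
    """
    wells, truth = generate_screen(cfg)
    normalized = PlateNormalizer().fit(wells).transform(wells)
    samples = normalized[normalized["role"] == "sample"]
    agg = aggregate_replicates(samples)
    matrix = agg.pivot(index="reagent_id", columns="assay", values="value")

    hit_input = pd.DataFrame({"gene": matrix.index})
    if cfg.replicates >= 2:
        per_rep = (
            samples[samples["assay"] == EPISTASIS_ASSAYS[0]]
            .groupby(["reagent_id", "replicate"])["value"]
            .mean()
            .unstack("replicate")
        )
        reps = sorted(per_rep.columns)
        hit_input["value_primary"] = per_rep[reps[0]].reindex(matrix.index).to_numpy()
        hit_input["value_confirmation"] = per_rep[reps[1]].reindex(matrix.index).to_numpy()
        require_confirmation = True
    else:
        hit_input["value_primary"] = matrix[EPISTASIS_ASSAYS[0]].to_numpy()
        require_confirmation = False
    for assay in REPORTER_ASSAYS:
        hit_input[f"reporter_{assay}"] = matrix[assay].to_numpy()
    params = {"require_confirmation": require_confirmation, **(hit_params or {})}
    caller = HitCaller(**params).fit(hit_input)
    hit_table = caller.call(hit_input).set_index("gene")

    out = truth.set_index("gene_id").copy()
    out["validated"] = hit_table["validated"].reindex(out.index).fillna(False).astype(bool)
    validated_genes = out.index[out["validated"]]
    calls = classify_profiles(matrix.loc[validated_genes, list(EPISTASIS_ASSAYS)])
    for col in ("interval", "status", "confidence"):
        out[col] = calls[col].reindex(out.index)
    out["call_sign"] = calls["sign"].reindex(out.index)
    return out


def interval_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    **sim_kwargs,
) -> dict:
    """Pooled end-to-end recovery statistics over independent screens.

    Returns recovery of planted interval regulators (validated + correct
    interval + correct sign), the fraction of neutral genes left silent
    (not validated, or unassigned/ambiguous), and the pooled counts.
    """
    reg_correct = reg_total = noise_silent = noise_total = 0
    for k in range(n_seeds):
        cfg = SimConfig(seed=base_seed + k, **sim_kwargs)
        table = evaluate_screen(cfg)
        reg = table[table["regulator_class"].isin(INTERVALS)]
        ok = (
            reg["validated"]
            & (reg["interval"] == reg["regulator_class"])
            & (reg["call_sign"] == reg["sign"])
        )
        reg_correct += int(ok.sum())
        reg_total += len(reg)
        noise = table[table["regulator_class"] == "none"]
        silent = (~noise["validated"]) | noise["status"].isin(["unassigned", "ambiguous"])
        noise_silent += int(silent.sum())
        noise_total += len(noise)
    return {
        "recovery_rate": reg_correct / reg_total,
        "noise_silent_rate": noise_silent / noise_total,
        "n_regulators": reg_total,
        "n_noise": noise_total,
    }


def control_zprime_samples(
    effect: float,
    noise_sd: float,
    n_wells: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw positive/negative control populations under the well noise model
    (log10 effect plus additive Gaussian log-scale noise)."""
    pos = effect + rng.normal(0.0, noise_sd, n_wells)
    neg = rng.normal(0.0, noise_sd, n_wells)
    return pos, neg


def specificity_inputs_from_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Assemble SpecificityScorer inputs from an aggregated assay matrix."""
    from .simulate import JNK_ASSAYS

    return pd.DataFrame(
        {
            "gene": matrix.index,
            "pmapk_effect": matrix[EPISTASIS_ASSAYS[0]].to_numpy(),
            "jnk_rac1": matrix[JNK_ASSAYS[0]].to_numpy(),
            "jnk_pgn": matrix[JNK_ASSAYS[1]].to_numpy(),
            "pmet_gfp_effect": matrix[REPORTER_ASSAYS[0]].to_numpy(),
        }
    ).reset_index(drop=True)
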