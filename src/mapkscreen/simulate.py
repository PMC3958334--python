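"""Synthetic RNAi-screen generator with known ground truth.

Emulates the design of a genome-wide pMAPK immunofluorescence screen in
96-well plates: every plate carries negative-control wells (GFP dsRNA, the
normalization reference) and positive-control wells (mek dsRNA, which
abolishes the signal, and PTP-ER dsRNA, which raises it), sample wells are
assigned round-robin in gene order, and each assay/replicate is screened as
its own plate series.

Signal model (per well, on the log10 scale):

    log10(signal) = baseline + plate_effect + s * effect * y_c[assay] + eps

where ``y_c`` is the idealized interval profile of the gene's regulator
class, ``s`` is +1/-1 for negative/positive regulators, ``plate_effect ~
N(0, plate_effect_sd)`` is a per-plate multiplicative bias, and ``eps ~
N(0, noise_sd)``.  Additive Gaussian noise on the log scale (log-normal on
the raw signal) reflects the multiplicative error structure of
immunofluorescence intensities.

Beyond the three pathway-regulator classes, the generator plants two kinds
of confounder the downstream filters must catch: promoter-artifact genes,
which perturb the metallothionein expression system (hence every
pMet-driven assay *and* the two promoter-reporter assays, proportionally),
and JNK-nonspecific genes, which perturb the JNK assays as strongly as
pMAPK.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epistasis import EPISTASIS_ASSAYS, IDEAL_PROFILES, INTERVALS

#: Promoter-reporter validation assays (metallothionein-driven GFP / HA-RasV12).
REPORTER_ASSAYS: tuple[str, ...] = ("pMet_GFP", "pMet_HA_RasV12")
#: JNK-pathway specificity assays (RAC1^V12- and peptidoglycan-induced pJNK).
JNK_ASSAYS: tuple[str, ...] = ("RAC1V12_pJNK", "PGN_pJNK")
ALL_ASSAYS: tuple[str, ...] = EPISTASIS_ASSAYS + REPORTER_ASSAYS + JNK_ASSAYS

GENE_CLASSES: tuple[str, ...] = INTERVALS + ("none", "promoter-artifact", "jnk-nonspecific")

ROLES = ("sample", "neg_ctrl", "pos_ctrl_down", "pos_ctrl_up")

WELL_COLUMNS = ["plate", "well", "reagent_id", "role", "assay", "replicate", "signal", "cells"]


def _default_fractions() -> dict[str, float]:
    return {
        "none": 0.70,
        "RAS-RAF": 0.06,
        "RAF-MEK": 0.06,
        "MEK-MAPK": 0.08,
        "promoter-artifact": 0.05,
        "jnk-nonspecific": 0.05,
    }


@dataclass
class SimConfig:
    """Screen-simulation parameters.

    Parameters
    ----------
    n_genes : number of sample reagents (one gene per reagent).
    class_fractions : proportion of genes per regulator class; must sum to 1.
    effect_size : |Delta| on the log10 normalized scale for every
        non-neutral gene (1.0 = tenfold change in the driven assays).
    noise_sd : per-well Gaussian noise sd on the log10 scale.
    plate_effect_sd : per-plate multiplicative bias sd on the log10 scale.
    wells_per_plate : plate capacity (96-well format).
    n_neg_controls_per_plate : GFP-dsRNA wells per plate (>= 1).
    n_pos_controls_per_plate : wells per plate for *each* positive-control
        reagent (mek and PTP-ER).
    replicates : wells per gene per assay (independent plate series).
    seed : RNG seed; fixed seed gives byte-identical output.
    baseline_log10 : log10 of the negative-control signal level (a.u.).
    pos_ctrl_down_effect / pos_ctrl_up_effect : log10 effect of the mek /
        PTP-ER control reagents. Defaults place the control separations in
        the Z'-factor range observed for this assay format (~0.64 strong,
        ~0.18 weak).
    promoter_coupling : reporter-assay effect of a promoter-artifact gene
        as a fraction of its pMAPK effect.
    plate_drift : optional linear log10 drift per plate index (screening-
        order trend), default off.
    """

    n_genes: int = 300
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_size: float = 1.0
    noise_sd: float = 0.06
    plate_effect_sd: float = 0.05
    wells_per_plate: int = 96
    n_neg_controls_per_plate: int = 4
    n_pos_controls_per_plate: int = 2
    replicates: int = 2
    seed: int = 0
    baseline_log10: float = 3.0
    pos_ctrl_down_reagent: str = "mek"
    pos_ctrl_down_effect: float = -1.0
    pos_ctrl_up_reagent: str = "PTP-ER"
    pos_ctrl_up_effect: float = 0.45
    neg_ctrl_reagent: str = "GFP"
    promoter_coupling: float = 1.0
    plate_drift: float = 0.0
    mean_cells: float = 500.0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown regulator class(es): {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")
        if min(self.noise_sd, self.plate_effect_sd) < 0:
            raise ValueError("noise_sd and plate_effect_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_neg_controls_per_plate < 1 or self.n_pos_controls_per_plate < 1:
            raise ValueError("at least one control well of each kind per plate")
        if self.samples_per_plate < 1:
            raise ValueError("plate layout leaves no sample wells")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @property
    def samples_per_plate(self) -> int:
        return (
            self.wells_per_plate
            - self.n_neg_controls_per_plate
            - 2 * self.n_pos_controls_per_plate
        )

    @property
    def n_plates(self) -> int:
        return -(-self.n_genes // self.samples_per_plate)  # ceil


def _class_counts(cfg: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes over class fractions."""
    classes = [c for c in GENE_CLASSES if c in cfg.class_fractions]
    exact = {c: cfg.class_fractions[c] * cfg.n_genes for c in classes}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = cfg.n_genes - sum(counts.values())
    by_remainder = sorted(classes, key=lambda c: (counts[c] - exact[c], c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def make_ground_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene ground truth: class, regulator sign, effect size."""
    counts = _class_counts(cfg)
    classes = np.concatenate([[c] * n for c, n in counts.items()]) if counts else []
    classes = np.asarray(classes, dtype=object)
    rng.shuffle(classes)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    sign = np.where(
        classes == "none", "none", np.where(rng.random(cfg.n_genes) < 0.5, "positive", "negative")
    )
    effect = np.where(classes == "none", 0.0, cfg.effect_size)
    return pd.DataFrame(
        {"gene_id": genes, "regulator_class": classes, "sign": sign, "effect": effect}
    )


def expected_effects(truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Expected log10 normalized value per gene x assay (the noise-free screen).

    Encodes the class semantics: interval regulators follow their idealized
    profile over the six epistasis assays; promoter artifacts perturb every
    pMet-driven assay plus the two reporter assays; JNK-nonspecific genes
    look like MEK-MAPK regulators but hit the JNK assays equally.
    """
    n = len(truth)
    eff = pd.DataFrame(0.0, index=truth["gene_id"], columns=list(ALL_ASSAYS))
    s = np.where(truth["sign"] == "positive", -1.0, np.where(truth["sign"] == "negative", 1.0, 0.0))
    amp = (s * truth["effect"].to_numpy())
    cls = truth["regulator_class"].to_numpy()
    for interval in INTERVALS:
        m = cls == interval
        if m.any():
            eff.loc[truth.loc[m, "gene_id"], list(EPISTASIS_ASSAYS)] = np.outer(
                amp[m], IDEAL_PROFILES[interval]
            )
    m = cls == "promoter-artifact"
    if m.any():
        eff.loc[truth.loc[m, "gene_id"], list(EPISTASIS_ASSAYS)] = amp[m][:, None] * np.ones(
            (1, len(EPISTASIS_ASSAYS))
        )
        eff.loc[truth.loc[m, "gene_id"], list(REPORTER_ASSAYS)] = (
            cfg.promoter_coupling * amp[m][:, None] * np.ones((1, len(REPORTER_ASSAYS)))
        )
    m = cls == "jnk-nonspecific"
    if m.any():
        eff.loc[truth.loc[m, "gene_id"], list(EPISTASIS_ASSAYS)] = amp[m][:, None] * np.ones(
            (1, len(EPISTASIS_ASSAYS))
        )
        eff.loc[truth.loc[m, "gene_id"], list(JNK_ASSAYS)] = amp[m][:, None] * np.ones(
            (1, len(JNK_ASSAYS))
        )
    return eff


def _well_labels(n: int) -> list[str]:
    rows = "ABCDEFGH"
    labels = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n <= len(labels):
        return labels[:n]
    return [f"W{i + 1:03d}" for i in range(n)]  # oversized virtual plates


def generate_screen(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full screen.

    Returns
    -------
    (wells, ground_truth)
        ``wells`` has one row per well with columns ``plate, well,
        reagent_id, role, assay, replicate, signal, cells``; ``ground_truth``
        one row per gene.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = make_ground_truth(cfg, rng)
    eff = expected_effects(truth, cfg)

    spp = cfg.samples_per_plate
    n_plates = cfg.n_plates
    genes = truth["gene_id"].to_numpy()
    # round-robin assignment in gene order
    plate_of_gene = np.arange(cfg.n_genes) % n_plates

    frames = []
    labels = _well_labels(cfg.wells_per_plate)
    for assay in ALL_ASSAYS:
        for rep in range(1, cfg.replicates + 1):
            plate_bias = rng.normal(0.0, cfg.plate_effect_sd, n_plates)
            plate_bias += cfg.plate_drift * np.arange(n_plates)
            for p in range(n_plates):
                sample_genes = genes[plate_of_gene == p]
                reagents = np.concatenate(
                    [
                        sample_genes,
                        [cfg.neg_ctrl_reagent] * cfg.n_neg_controls_per_plate,
                        [cfg.pos_ctrl_down_reagent] * cfg.n_pos_controls_per_plate,
                        [cfg.pos_ctrl_up_reagent] * cfg.n_pos_controls_per_plate,
                    ]
                )
                roles = np.concatenate(
                    [
                        ["sample"] * len(sample_genes),
                        ["neg_ctrl"] * cfg.n_neg_controls_per_plate,
                        ["pos_ctrl_down"] * cfg.n_pos_controls_per_plate,
                        ["pos_ctrl_up"] * cfg.n_pos_controls_per_plate,
                    ]
                )
                delta = np.zeros(len(reagents))
                delta[: len(sample_genes)] = eff.loc[sample_genes, assay].to_numpy()
                if assay in EPISTASIS_ASSAYS:
                    # control reagents act on the pathway itself
                    delta[roles == "pos_ctrl_down"] = cfg.pos_ctrl_down_effect
                    delta[roles == "pos_ctrl_up"] = cfg.pos_ctrl_up_effect
                log10_signal = (
                    cfg.baseline_log10
                    + plate_bias[p]
                    + delta
                    + rng.normal(0.0, cfg.noise_sd, len(reagents))
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": f"{assay}-r{rep}-p{p + 1:03d}",
                            "well": labels[: len(reagents)],
                            "reagent_id": reagents,
                            "role": roles,
                            "assay": assay,
                            "replicate": rep,
                            "signal": 10.0**log10_signal,
                            "cells": rng.poisson(cfg.mean_cells, len(reagents)),
                        }
                    )
                )
    wells = pd.concat(frames, ignore_index=True)
    return wells, truth


def config_to_text(cfg: SimConfig) -> str:
    """Serialize a SimConfig as a flat ``key: value`` text block."""
    lines = []
    for key, value in asdict(cfg).items():
        if isinstance(value, dict):
            value = ", ".join(f"{k}={v}" for k, v in value.items())
        lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"


def write_screen(wells: pd.DataFrame, truth: pd.DataFrame, cfg: SimConfig, out_dir) -> dict:
    """Write wells/ground-truth TSVs and the config snapshot to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wells": out / "wells.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "config": out / "sim_config.txt",
    }
    wells.to_csv(paths["wells"], sep="\t", index=False, float_format="%.10g")
    truth.to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.10g")
    paths["config"].write_text(config_to_text(cfg))
    return {k: str(v) for k, v in paths.items()}
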