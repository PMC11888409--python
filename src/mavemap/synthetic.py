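"""Synthetic TileSeq-style selection experiments with known ground truth.

Emulates a pooled variant-effect assay: a saturation-mutagenesis library of
clones (Poisson number of codon substitutions each) is sequenced in short
amplicon tiles before and after a selection step, alongside a wild-type
control that measures per-variant sequencing-error frequencies.  Every
variant carries a known true effect (1 = wild-type-like, 0 = null), so the
whole downstream scoring pipeline can be validated against ground truth.

The missense effect distribution is a two-mode Gaussian mixture (a damaged
mode at 0 and a tolerated mode at 1), matching the bimodal score
distributions such assays produce; the within-mode shape is a modelling
choice, see the methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .variants import (
    VariantClass,
    VariantDescriptor,
    enumerate_variant_space,
    protein_sequence,
)

_SENSE_CODONS = tuple(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)

LIBRARY_CONDITIONS = ("pre", "post")
WT_CONDITIONS = ("wt_pre", "wt_post")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic selection experiment.

    Defaults follow the regime of a ~150-residue ORF sequenced at 1.3
    million reads per tile with two biological replicates: mean codon
    substitutions per clone 0.64 and a damaged-mode missense fraction of
    0.15 (activity-assay preset; the abundance preset uses 0.83 / 0.18).
    """

    L: int = 153
    depth: int = 1_300_000
    replicates: int = 2
    n_tiles: int = 5
    clone_lambda: float = 0.64
    deleterious_fraction: float = 0.15
    mode_sd: float = 0.08
    error_rate_shape: float = 1.5
    error_rate_scale: float = 2e-6
    selection_floor: float = 0.05
    n_clones: int = 1_000_000
    codon_sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.deleterious_fraction <= 1.0:
            raise ValueError("deleterious_fraction must be in [0, 1]")
        if self.clone_lambda <= 0:
            raise ValueError("clone_lambda must be positive")
        if not 0.0 <= self.selection_floor <= 1.0:
            raise ValueError("selection_floor must be in [0, 1]")
        if self.replicates < 1 or self.n_tiles < 1:
            raise ValueError("replicates and n_tiles must be >= 1")

    @classmethod
    def abundance_preset(cls, **overrides) -> "SimulationConfig":
        """Preset mirroring the abundance-assay regime."""
        defaults = dict(clone_lambda=0.83, deleterious_fraction=0.18)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TruthTable:
    """Ground truth per variant: the true effect and the per-variant
    sequencing-error frequency shared by library and control samples."""

    frame: pd.DataFrame  # columns: hgvs_p position from_aa to_aa vclass mode true_effect error_freq

    def __post_init__(self) -> None:
        required = {"hgvs_p", "position", "vclass", "true_effect", "error_freq"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")

    @property
    def variants(self) -> list[VariantDescriptor]:
        return [
            VariantDescriptor(int(r.position), r.from_aa, r.to_aa)
            for r in self.frame.itertuples()
        ]


@dataclass
class ReferenceSets:
    """Labelled reference variants for benchmarking and calibration."""

    positives: list[str]
    negatives: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"reference sets overlap: {sorted(overlap)[:5]}")


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Per-stage RNG substream derived from one root seed."""
    digest = hashlib.sha256(stage.encode()).digest()[:4]
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def random_orf(L: int, seed: int) -> str:
    """A reproducible ORF of L sense codons plus a TAA stop."""
    rng = _substream(seed, "orf")
    codons = rng.choice(len(_SENSE_CODONS), size=L)
    return "".join(_SENSE_CODONS[i] for i in codons) + "TAA"


def tile_of_position(position: int, L: int, n_tiles: int) -> int:
    """1-based tile index; the ORF is split into n_tiles equal windows."""
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside [1, {L}]")
    return 1 + (position - 1) * n_tiles // L


def simulate_truth(
    variants: list[VariantDescriptor], config: SimulationConfig
) -> TruthTable:
    """Draw true effects and error frequencies for every variant.

    Missense effects come from a two-mode mixture: with probability
    ``deleterious_fraction`` the damaged mode N(0, mode_sd), otherwise the
    tolerated mode N(1, mode_sd).  Synonymous variants are fixed at 1 and
    nonsense at 0.  Error frequencies are i.i.d. Gamma(shape, scale).
    """
    rng = _substream(config.seed, "truth")
    n = len(variants)
    vclass = np.array([v.vclass.value for v in variants])
    effect = np.empty(n)
    mode = np.full(n, "", dtype=object)

    is_mis = vclass == VariantClass.missense.value
    n_mis = int(is_mis.sum())
    damaged = rng.random(n_mis) < config.deleterious_fraction
    centers = np.where(damaged, 0.0, 1.0)
    effect[is_mis] = rng.normal(centers, config.mode_sd)
    mode[is_mis] = np.where(damaged, "damaged", "tolerated")

    effect[vclass == VariantClass.synonymous.value] = 1.0
    effect[vclass == VariantClass.nonsense.value] = 0.0
    mode[vclass == VariantClass.nonsense.value] = "damaged"
    mode[vclass == VariantClass.synonymous.value] = "tolerated"

    error_freq = rng.gamma(config.error_rate_shape, config.error_rate_scale, size=n)

    frame = pd.DataFrame(
        {
            "hgvs_p": [v.hgvs_p for v in variants],
            "position": [v.position for v in variants],
            "from_aa": [v.from_aa for v in variants],
            "to_aa": [v.to_aa for v in variants],
            "vclass": vclass,
            "mode": mode,
            "true_effect": effect,
            "error_freq": error_freq,
        }
    )
    return TruthTable(frame)


def selection_weight(effect: np.ndarray, floor: float) -> np.ndarray:
    """Survival s(e) = floor + (1 - floor) * clamp(e, 0, 1)."""
    return floor + (1.0 - floor) * np.clip(effect, 0.0, 1.0)


def _wt_row(tile: int, condition: str, replicate: int, count: int, depth: int) -> dict:
    return {
        "condition": condition,
        "replicate": replicate,
        "tile": tile,
        "hgvs_p": "p.=",
        "position": 0,
        "from_aa": "",
        "to_aa": "",
        "vclass": "wt",
        "count": count,
        "depth": depth,
    }


def simulate_count_tables(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample tiled read counts for the library and the WT control.

    Returns two long-format count tables (columns condition, replicate,
    tile, hgvs_p, position, from_aa, to_aa, vclass, count, depth): one with
    pre/post library conditions, one with the matching wt_pre/wt_post
    control conditions whose only signal is sequencing error.
    """
    rng = _substream(config.seed, "counts")
    tf = truth.frame
    n = len(tf)
    if n == 0:
        raise ValueError("empty truth table")

    # finite clone pool: total substitutions ~ Poisson, assigned uniformly
    total_subs = rng.poisson(config.clone_lambda * config.n_clones)
    copies = rng.multinomial(total_subs, np.full(n, 1.0 / n))
    f_clone = copies / config.n_clones

    s = selection_weight(tf["true_effect"].to_numpy(), config.selection_floor)
    err = tf["error_freq"].to_numpy()
    tiles = np.array(
        [tile_of_position(p, config.L, config.n_tiles) for p in tf["position"]]
    )

    lib_rows: list[dict] = []
    wt_rows: list[dict] = []
    for tile in range(1, config.n_tiles + 1):
        idx = np.flatnonzero(tiles == tile)
        fc = f_clone[idx]
        wt_frac = 1.0 - fc.sum()
        if wt_frac <= 0:
            raise RuntimeError(
                f"tile {tile}: clone frequencies exceed 1 (library too dense)"
            )
        # post-selection clone frequencies: reweight by survival, WT remainder
        # survives with s(1) = 1
        w = fc * s[idx]
        z = w.sum() + wt_frac
        f_post = w / z
        exp_freq = {
            "pre": fc + err[idx],
            "post": f_post + err[idx],
            "wt_pre": err[idx],
            "wt_post": err[idx],
        }
        sub = tf.iloc[idx]
        for condition, freqs in exp_freq.items():
            wt_freq = 1.0 - freqs.sum()
            if wt_freq <= 0:
                raise RuntimeError(f"tile {tile} {condition}: frequencies exceed 1")
            p = np.append(freqs, wt_freq)
            for rep in range(1, config.replicates + 1):
                counts = rng.multinomial(config.depth, p)
                rows = lib_rows if condition in LIBRARY_CONDITIONS else wt_rows
                for j, row in enumerate(sub.itertuples()):
                    rows.append(
                        {
                            "condition": condition,
                            "replicate": rep,
                            "tile": tile,
                            "hgvs_p": row.hgvs_p,
                            "position": int(row.position),
                            "from_aa": row.from_aa,
                            "to_aa": row.to_aa,
                            "vclass": row.vclass,
                            "count": int(counts[j]),
                            "depth": config.depth,
                        }
                    )
                rows.append(
                    _wt_row(tile, condition, rep, int(counts[-1]), config.depth)
                )

    return pd.DataFrame(lib_rows), pd.DataFrame(wt_rows)


def simulate_reference_sets(
    truth: TruthTable,
    n_pos: int = 85,
    n_neg: int = 100,
    label_noise: float = 0.0,
    seed: int = 0,
) -> ReferenceSets:
    """Sample disjoint pathogenic / proxy-benign reference variant sets.

    Positives are drawn from damaged-mode missense variants and negatives
    from tolerated-mode ones; a ``label_noise`` fraction of each set is
    drawn from the wrong mode instead (``label_noise = 1`` inverts the
    labels entirely).  Default sizes mirror a typical clinical positive set
    (85) paired with a population proxy-benign set (100).
    """
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must be in [0, 1]")
    rng = _substream(seed, "refsets")
    tf = truth.frame
    mis = tf[tf["vclass"] == VariantClass.missense.value]
    damaged = mis.loc[mis["mode"] == "damaged", "hgvs_p"].to_list()
    tolerated = mis.loc[mis["mode"] == "tolerated", "hgvs_p"].to_list()

    k_pos_wrong = round(label_noise * n_pos)
    k_neg_wrong = round(label_noise * n_neg)
    need_damaged = (n_pos - k_pos_wrong) + k_neg_wrong
    need_tolerated = (n_neg - k_neg_wrong) + k_pos_wrong
    if need_damaged > len(damaged) or need_tolerated > len(tolerated):
        raise ValueError(
            f"requested sets need {need_damaged} damaged / {need_tolerated} "
            f"tolerated variants but only {len(damaged)} / {len(tolerated)} exist"
        )

    pick_d = rng.choice(len(damaged), size=need_damaged, replace=False)
    pick_t = rng.choice(len(tolerated), size=need_tolerated, replace=False)
    damaged_pick = [damaged[i] for i in pick_d]
    tolerated_pick = [tolerated[i] for i in pick_t]

    positives = damaged_pick[: n_pos - k_pos_wrong] + tolerated_pick[: k_pos_wrong]
    negatives = (
        tolerated_pick[k_pos_wrong:] + damaged_pick[n_pos - k_pos_wrong :]
    )
    assert len(negatives) == n_neg
    return ReferenceSets(
        positives=positives,
        negatives=negatives,
        provenance={
            "positives": "synthetic damaged-mode sample",
            "negatives": "synthetic tolerated-mode sample",
            "label_noise": str(label_noise),
        },
    )


def simulate_run(config: SimulationConfig) -> dict:
    """Convenience wrapper: ORF -> variant space -> truth -> count tables."""
    orf = config.codon_sequence or random_orf(config.L, config.seed)
    variants = enumerate_variant_space(config.L, orf)
    truth = simulate_truth(variants, config)
    lib_counts, wt_counts = simulate_count_tables(truth, config)
    return {
        "orf": orf,
        "wt_sequence": protein_sequence(orf),
        "variants": variants,
        "truth": truth,
        "lib_counts": lib_counts,
        "wt_counts": wt_counts,
    }


def write_run_directory(run: dict, config: SimulationConfig, out_dir: str | Path) -> Path:
    """Persist a simulated run: count TSVs, truth TSV, config YAML, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run["lib_counts"].to_csv(out / "library_counts.tsv", sep="\t", index=False)
    run["wt_counts"].to_csv(out / "wt_control_counts.tsv", sep="\t", index=False)
    run["truth"].frame.to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(config)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "orf": run["orf"],
        "wt_sequence": run["wt_sequence"],
        "n_variants": len(run["variants"]),
        "files": [
            "library_counts.tsv",
            "wt_control_counts.tsv",
            "truth.tsv",
            "config.yaml",
        ],
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
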