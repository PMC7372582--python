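"""Synthetic multi-cell-line Cell Painting screens with known ground truth.

The generator emulates the data layer of a high-content phenotypic screen
run across a panel of esophageal adenocarcinoma (EAC) cell lines plus
tissue-matched control lines:

* per-cell morphology tables (one row per segmented cell, hundreds of
  named features), organised into plates, wells and image sites;
* a reference library of annotated compounds spanning several mechanistic
  classes, dosed at three concentrations;
* a screening library containing a small number of planted compounds that
  are selectively active in a subset of the cancer lines and in no control
  line;
* plate-level multiplicative effects, Poisson cell counts, and a
  configurable rate of low-cell-count artifact images.

Every downstream stage (preprocessing, MoA classification, hit calling,
clustering) can therefore be tested against exact ground truth.  Feature
values follow an additive model per cell::

    x = plate_effect * (baseline[line] + signature[class] * dose_scale + noise)

with the plate effect multiplicative (log-normal per plate and feature),
class signatures sparse (a random fraction of features shifted up or down
by ``effect_size`` cell-level standard deviations) and cell-level noise
Gaussian.  Nuclei counts per well are the summed per-image cell counts from
the same generator; selectively lethal compounds reduce counts only in
their truly active lines.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "ScreenGroundTruth",
    "SyntheticScreen",
    "generate_screen",
    "ground_truth_hit_set",
]

#: metadata columns used by all tables in the package; everything else is a feature
META_COLUMNS = (
    "cell_line",
    "plate",
    "well",
    "site",
    "cell_id",
    "compound",
    "concentration",
    "role",
    "n_cells",
    "nuclei_count",
    "dose",
    "moa_class",
)

DEFAULT_CLASSES = (
    "DMSO",
    "actin_disruptor",
    "dna_damage",
    "hdac_inhibitor",
    "hsp90_inhibitor",
    "kinase_inhibitor",
    "microtubule_disruptor",
    "proteasome_inhibitor",
)

_PLATE_SHAPES = {6: (2, 3), 24: (4, 6), 96: (8, 12), 384: (16, 24), 1536: (32, 48)}


def well_labels(wells_per_plate: int) -> list[str]:
    """Row-letter + zero-padded-column labels ("A01".."P24") for a plate size."""
    if wells_per_plate in _PLATE_SHAPES:
        n_rows, n_cols = _PLATE_SHAPES[wells_per_plate]
    else:
        n_rows = max(r for r in range(1, 53) if wells_per_plate % r == 0 and r * r <= wells_per_plate)
        n_cols = wells_per_plate // n_rows
    if n_rows > 52:
        raise ValueError(f"cannot lay out {wells_per_plate} wells with <=52 rows")
    letters = list(string.ascii_uppercase) + ["A" + c for c in string.ascii_uppercase]
    return [f"{letters[r]}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)]


@dataclass(frozen=True)
class ScreenConfig:
    """Study design for one synthetic screen.

    Defaults describe the full-scale assay: an 8-line panel (6 EAC, 2
    control), 733 morphology features, 384-well plates with ~300 cells per
    image, a reference library of 7 mechanistic classes (plus DMSO) dosed
    at 0.1/1/10 uM, and a single-dose screening library of 500 compounds
    containing 20 planted EAC-selective actives with a 2.0 SD phenotypic
    effect.  Tests and examples shrink these numbers explicitly.
    """

    n_cell_lines: int = 8
    n_control_lines: int = 2
    n_features: int = 733
    wells_per_plate: int = 384
    dmso_fraction: float = 1.0 / 12.0
    moa_classes: tuple[str, ...] = DEFAULT_CLASSES
    compounds_per_class: int = 5
    replicates_per_dose: int = 2
    doses: tuple[float, ...] = (0.1, 1.0, 10.0)
    dose_scaling: tuple[float, ...] = (0.25, 0.6, 1.0)
    effect_size: float = 2.0
    signature_fraction: float = 0.10
    n_screen_compounds: int = 500
    n_selective: int = 20
    n_group_toxic: int = 0
    screen_dose: float = 10.0
    selective_viability_factor: float = 0.3
    line_specific_signatures: bool = False
    plate_effect_sd: float = 0.05
    cells_per_image_mean: float = 300.0
    sites_per_well: int = 1
    artifact_image_rate: float = 0.02
    artifact_max_cells: int = 19
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (5.0, 15.0)
    include_reference: bool = True
    include_screen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_cell_lines": self.n_cell_lines,
            "n_control_lines": self.n_control_lines,
            "n_features": self.n_features,
            "wells_per_plate": self.wells_per_plate,
            "sites_per_well": self.sites_per_well,
            "cells_per_image_mean": self.cells_per_image_mean,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 < self.dmso_fraction < 1.0:
            raise ValueError(f"dmso_fraction must lie in (0, 1), got {self.dmso_fraction}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0.0 <= self.artifact_image_rate <= 1.0:
            raise ValueError(f"artifact_image_rate must lie in [0, 1], got {self.artifact_image_rate}")
        if self.n_control_lines >= self.n_cell_lines:
            raise ValueError("n_control_lines must be smaller than n_cell_lines")
        if self.n_cell_lines == 8 and self.n_control_lines != 2:
            raise ValueError("an 8-line panel carries exactly 2 control lines")
        if len(self.doses) != len(self.dose_scaling):
            raise ValueError("dose_scaling must provide one factor per dose")
        if "DMSO" not in self.moa_classes:
            raise ValueError("moa_classes must include 'DMSO'")
        if self.n_selective > self.n_screen_compounds:
            raise ValueError("n_selective cannot exceed n_screen_compounds")
        if self.n_selective + self.n_group_toxic > self.n_screen_compounds:
            raise ValueError("n_selective + n_group_toxic cannot exceed n_screen_compounds")

    @property
    def eac_lines(self) -> tuple[str, ...]:
        n_eac = self.n_cell_lines - self.n_control_lines
        return tuple(f"EAC{i + 1}" for i in range(n_eac))

    @property
    def control_lines(self) -> tuple[str, ...]:
        return tuple(f"CTRL{i + 1}" for i in range(self.n_control_lines))

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return self.eac_lines + self.control_lines

    @property
    def feature_names(self) -> list[str]:
        return [f"ft_{i + 1:04d}" for i in range(self.n_features)]

    def dose_scale(self, dose: float) -> float:
        for d, s in zip(self.doses, self.dose_scaling):
            if d == dose:
                return s
        if dose == self.screen_dose:
            return self.dose_scaling[-1]
        raise ValueError(f"unknown dose {dose}")


@dataclass
class ScreenGroundTruth:
    """Planted truth for one synthetic screen."""

    true_class: dict[str, str]
    active_lines: dict[str, frozenset[str]]
    dose_response: dict[str, dict[float, float]]
    eac_lines: tuple[str, ...]
    control_lines: tuple[str, ...]
    selective_compounds: tuple[str, ...]
    viability_factor: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, lines in self.active_lines.items():
            if compound in self.selective_compounds:
                if len(lines & set(self.eac_lines)) < 2 or lines & set(self.control_lines):
                    raise ValueError(
                        f"planted selective compound {compound} must be active in >=2 EAC lines and no control line"
                    )


def ground_truth_hit_set(truth: ScreenGroundTruth, min_eac_lines: int = 2) -> set[str]:
    """Planted compounds active in >= ``min_eac_lines`` EAC lines and no control line."""
    if min_eac_lines < 1:
        raise ValueError(f"min_eac_lines must be >= 1, got {min_eac_lines}")
    eac = set(truth.eac_lines)
    ctrl = set(truth.control_lines)
    return {
        c
        for c, lines in truth.active_lines.items()
        if len(lines & eac) >= min_eac_lines and not lines & ctrl
    }


def _layout_plates(
    cfg: ScreenConfig, entries: list[tuple[str, float]], prefix: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Place (compound, dose) entries plus per-plate DMSO wells onto plates."""
    labels = well_labels(cfg.wells_per_plate)
    n_dmso = max(2, int(round(cfg.dmso_fraction * cfg.wells_per_plate)))
    capacity = cfg.wells_per_plate - n_dmso
    rows = []
    for start in range(0, len(entries), capacity):
        chunk = entries[start : start + capacity]
        plate = f"{prefix}{start // capacity + 1}"
        content: list[tuple[str, float, str]] = [("DMSO", 0.0, "vehicle_control")] * n_dmso
        content += [(c, d, "treatment") for c, d in chunk]
        wells = rng.permutation(len(labels))[: len(content)]
        for w, (compound, conc, role) in zip(np.sort(wells), content):
            rows.append((plate, labels[w], compound, conc, role))
    out = pd.DataFrame(rows, columns=["plate", "well", "compound", "concentration", "role"])
    # shuffle which well gets which content, deterministically
    for plate, idx in out.groupby("plate").groups.items():
        perm = rng.permutation(len(idx))
        cols = ["compound", "concentration", "role"]
        out.loc[idx, cols] = out.loc[idx, cols].to_numpy()[perm]
    return out


@dataclass
class SyntheticScreen:
    """Generated screen: plate maps, annotations, truth, and lazy cell tables.

    Per-cell feature tables can be large, so they are materialised one cell
    line at a time via :meth:`cell_features`; plate maps, reference
    annotations and nuclei counts are small and eager.
    """

    config: ScreenConfig
    platemap: pd.DataFrame
    annotations: pd.DataFrame
    truth: ScreenGroundTruth
    _signatures: dict[tuple[str, str], np.ndarray] = field(repr=False, default_factory=dict)
    _baselines: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return self.config.cell_lines

    def platemap_for(self, line: str) -> pd.DataFrame:
        pm = self.platemap[self.platemap["cell_line"] == line]
        if pm.empty:
            raise ValueError(f"unknown cell line {line!r}")
        return pm.reset_index(drop=True)

    def _line_rng(self, line: str, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, self.cell_lines.index(line), stream])

    def _image_counts(self, line: str) -> pd.DataFrame:
        """Cell count per image site, independent of the feature draw."""
        cfg = self.config
        rng = self._line_rng(line, 11)
        pm = self.platemap_for(line)
        rows = []
        for plate, well, compound in pm[["plate", "well", "compound"]].itertuples(index=False):
            mean = cfg.cells_per_image_mean * self.truth.viability_factor.get(compound, {}).get(line, 1.0)
            for site in range(1, cfg.sites_per_well + 1):
                artifact = rng.random() < cfg.artifact_image_rate
                if artifact:
                    n = int(rng.integers(0, cfg.artifact_max_cells + 1))
                else:
                    n = int(rng.poisson(mean))
                rows.append((plate, well, site, n, artifact))
        return pd.DataFrame(rows, columns=["plate", "well", "site", "n_cells", "artifact"])

    def nuclei_counts(self, line: str | None = None, exclude_artifacts: bool = True) -> pd.DataFrame:
        """Per-well nuclei counts (summed over image sites) for viability analysis.

        By default artifact images — segmentation/imaging failures, not real
        biology — are excluded from the sum, emulating image-QC-aware
        counting; a well whose images are all artifacts gets a missing
        count.  ``exclude_artifacts=False`` sums raw counts.
        """
        lines = [line] if line is not None else list(self.cell_lines)
        frames = []
        for ln in lines:
            img = self._image_counts(ln)
            if exclude_artifacts:
                img = img.assign(n_cells=img["n_cells"].where(~img["artifact"]))
            counts = (
                img.groupby(["plate", "well"], as_index=False)["n_cells"]
                .sum(min_count=1)
                .rename(columns={"n_cells": "nuclei_count"})
            )
            counts.insert(0, "cell_line", ln)
            frames.append(counts)
        return pd.concat(frames, ignore_index=True)

    def _well_shift(self, line: str, compound: str, concentration: float) -> np.ndarray:
        cfg = self.config
        zero = np.zeros(cfg.n_features)
        if compound == "DMSO":
            return zero
        truth = self.truth
        klass = truth.true_class.get(compound)
        if klass is None or klass in ("DMSO", "inactive", "group_toxic"):
            return zero
        if compound in set(truth.selective_compounds) or compound.startswith("scr_"):
            if line not in truth.active_lines.get(compound, frozenset()):
                return zero
            sig = self._signatures[("__compound__", compound)]
        else:
            key = (line, klass) if cfg.line_specific_signatures else ("__shared__", klass)
            sig = self._signatures[key]
        return sig * truth.dose_response[compound].get(concentration, cfg.dose_scale(concentration))

    def cell_features(self, line: str) -> pd.DataFrame:
        """Materialise the per-cell feature table for one cell line."""
        cfg = self.config
        counts = self._image_counts(line)
        rng = self._line_rng(line, 13)
        pm = self.platemap_for(line).set_index(["plate", "well"])
        baseline = self._baselines[line]
        blocks: list[np.ndarray] = []
        meta_frames: list[pd.DataFrame] = []
        for plate, plate_counts in counts.groupby("plate", sort=False):
            plate_effect = np.exp(rng.normal(0.0, cfg.plate_effect_sd, cfg.n_features)).astype(np.float32)
            n_cells = plate_counts["n_cells"].to_numpy()
            total = int(n_cells.sum())
            if total == 0:
                continue
            means = np.empty((len(plate_counts), cfg.n_features), dtype=np.float32)
            for i, (well, n) in enumerate(zip(plate_counts["well"], n_cells)):
                compound = pm.loc[(plate, well), "compound"]
                conc = pm.loc[(plate, well), "concentration"]
                means[i] = baseline + self._well_shift(line, compound, conc)
            x = rng.standard_normal((total, cfg.n_features), dtype=np.float32)
            x *= cfg.noise_sd
            x += np.repeat(means, n_cells, axis=0)
            x *= plate_effect[None, :]
            blocks.append(x)
            meta_frames.append(
                pd.DataFrame(
                    {
                        "cell_line": line,
                        "plate": plate,
                        "well": np.repeat(plate_counts["well"].to_numpy(), n_cells),
                        "site": np.repeat(plate_counts["site"].to_numpy(), n_cells),
                        "cell_id": np.concatenate([np.arange(1, n + 1) for n in n_cells if n > 0]),
                    }
                )
            )
        features = pd.DataFrame(
            np.concatenate(blocks, axis=0) if blocks else np.empty((0, cfg.n_features), np.float32),
            columns=cfg.feature_names,
        )
        out = pd.concat(meta_frames, ignore_index=True) if meta_frames else pd.DataFrame(
            columns=["cell_line", "plate", "well", "site", "cell_id"]
        )
        return pd.concat([out, features], axis=1)

    def cells_by_line(self) -> dict[str, pd.DataFrame]:
        """Eager per-line tables; intended for small configurations only."""
        return {line: self.cell_features(line) for line in self.cell_lines}


def generate_screen(config: ScreenConfig) -> SyntheticScreen:
    """Build a synthetic screen: plate maps, annotations, ground truth, signatures.

    Deterministic given ``config.seed``; identical configs yield
    byte-identical tables.  Per-cell features are generated lazily per cell
    line (see :class:`SyntheticScreen`).
    """
    cfg = config
    rng_truth = np.random.default_rng([cfg.seed, 202])
    rng_layout = np.random.default_rng([cfg.seed, 101])

    compound_classes = [c for c in cfg.moa_classes if c != "DMSO"]
    true_class: dict[str, str] = {}
    active: dict[str, frozenset[str]] = {}
    dose_response: dict[str, dict[float, float]] = {}
    annotations_rows = []
    ref_entries: list[tuple[str, float]] = []
    all_lines = frozenset(cfg.cell_lines)

    signatures: dict[tuple[str, str], np.ndarray] = {}
    n_sig = max(1, int(round(cfg.signature_fraction * cfg.n_features)))

    def draw_signature(rng: np.random.Generator) -> np.ndarray:
        sig = np.zeros(cfg.n_features)
        idx = rng.choice(cfg.n_features, n_sig, replace=False)
        sig[idx] = rng.choice([-1.0, 1.0], n_sig) * cfg.effect_size * cfg.noise_sd
        return sig

    for klass in compound_classes:
        signatures[("__shared__", klass)] = draw_signature(rng_truth)
        for line in cfg.cell_lines:
            signatures[(line, klass)] = draw_signature(rng_truth)

    if cfg.include_reference:
        for klass in compound_classes:
            for j in range(cfg.compounds_per_class):
                name = f"ref_{klass}_{j + 1:02d}"
                true_class[name] = klass
                active[name] = all_lines
                dose_response[name] = {d: cfg.dose_scale(d) for d in cfg.doses}
                annotations_rows.append((name, klass))
                for dose in cfg.doses:
                    ref_entries += [(name, dose)] * cfg.replicates_per_dose

    screen_entries: list[tuple[str, float]] = []
    selective: list[str] = []
    viability: dict[str, dict[str, float]] = {}
    if cfg.include_screen and cfg.n_screen_compounds > 0:
        names = [f"scr_{i + 1:05d}" for i in range(cfg.n_screen_compounds)]
        picks = rng_truth.choice(cfg.n_screen_compounds, cfg.n_selective + cfg.n_group_toxic, replace=False)
        chosen = set(picks[: cfg.n_selective].tolist())
        group_toxic = set(picks[cfg.n_selective :].tolist())
        eac = list(cfg.eac_lines)
        for i, name in enumerate(names):
            if i in chosen:
                selective.append(name)
                k = int(rng_truth.integers(2, len(eac) + 1))
                lines = frozenset(rng_truth.choice(eac, k, replace=False).tolist())
                true_class[name] = str(rng_truth.choice(compound_classes))
                active[name] = lines
                signatures[("__compound__", name)] = draw_signature(rng_truth)
                viability[name] = {l: cfg.selective_viability_factor for l in lines}
            elif i in group_toxic:
                # viability effect shared within line roles: all EAC lines see one
                # factor, all control lines another, so line roles form response
                # groups without creating EAC-selective ground-truth hits
                true_class[name] = "group_toxic"
                active[name] = frozenset(cfg.cell_lines)
                f_eac = float(rng_truth.uniform(0.2, 1.0))
                f_ctrl = float(rng_truth.uniform(0.2, 1.0))
                viability[name] = {
                    **{l: f_eac for l in cfg.eac_lines},
                    **{l: f_ctrl for l in cfg.control_lines},
                }
            else:
                true_class[name] = "inactive"
                active[name] = frozenset()
            dose_response[name] = {cfg.screen_dose: cfg.dose_scale(cfg.screen_dose)}
            screen_entries.append((name, cfg.screen_dose))

    truth = ScreenGroundTruth(
        true_class=true_class,
        active_lines=active,
        dose_response=dose_response,
        eac_lines=cfg.eac_lines,
        control_lines=cfg.control_lines,
        selective_compounds=tuple(selective),
        viability_factor=viability,
    )

    ref_layout = _layout_plates(cfg, ref_entries, "REF", rng_layout) if ref_entries else None
    scr_layout = _layout_plates(cfg, screen_entries, "SCR", rng_layout) if screen_entries else None

    frames = []
    for line in cfg.cell_lines:
        for layout in (ref_layout, scr_layout):
            if layout is None:
                continue
            pm = layout.copy()
            pm["plate"] = line + "-" + pm["plate"]
            pm.insert(0, "cell_line", line)
            frames.append(pm)
    platemap = pd.concat(frames, ignore_index=True)

    rng_base = np.random.default_rng([cfg.seed, 303])
    lo, hi = cfg.baseline_range
    baselines = {line: rng_base.uniform(lo, hi, cfg.n_features) for line in cfg.cell_lines}

    annotations = pd.DataFrame(annotations_rows, columns=["compound", "moa_class"])
    return SyntheticScreen(
        config=cfg,
        platemap=platemap,
        annotations=annotations,
        truth=truth,
        _signatures=signatures,
        _baselines=baselines,
    )


def small_config(**overrides) -> ScreenConfig:
    """A desk-scale configuration used across tests and examples."""
    defaults = dict(
        n_cell_lines=4,
        n_control_lines=1,
        n_features=40,
        wells_per_plate=96,
        dmso_fraction=1.0 / 6.0,
        compounds_per_class=2,
        replicates_per_dose=1,
        n_screen_compounds=30,
        n_selective=5,
        cells_per_image_mean=30.0,
        seed=0,
    )
    defaults.update(overrides)
    return ScreenConfig(**defaults)
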