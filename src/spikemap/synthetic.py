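"""Synthetic spike generator with ground truth.

Builds cartoon wheat inflorescences that carry the statistical and spatial
structure the downstream analysis assumes: a central rachis column (with an
inner vasculature core) spanning the apical-basal (y) axis, and at each of 13
phytomer positions an axillary-meristem (AM) cluster with an adjacent
leaf-ridge (LR) cluster on alternating flanks.  Counts are Poisson draws from
per-domain gene programs with a lognormal per-cell size factor; designated
gradient genes follow a log-linear profile along y; blank barcodes are drawn
so the expected blank fraction of detections matches the configured rate;
small sub-threshold segmentation artifacts and low-count cells are injected
at configurable fractions.

The generator is fully deterministic given a spec and seed, and returns a
:class:`SyntheticTruth` (true domains, AM/LR groups with positions 1..13,
gradient parameters, designed marker genes) for recovery testing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Polygon, box

from . import io as _io
from .errors import FormatError

CELL_SIDE = 10.0  # µm, side of one convex cell tile
BAND_HEIGHT = 50.0  # µm of y axis per phytomer position (5 rows of cells)
ARTIFACT_SIDE = 3.0  # µm; 3x3x10 = 90 µm³, well below the 500 µm³ threshold
N_BLANKS = 15  # blank barcodes in the MERSCOPE codebook

# per-position LR sizes: basal ridges (LR1-4) are large and variable, central
# ridges (LR8-11) small and uniform, emulating the measured section counts
LR_SIZE_PROFILE = (53, 36, 25, 16, 15, 14, 13, 11, 13, 12, 14, 12, 12)


@dataclass(frozen=True)
class GradientGene:
    """A gene whose rate varies log-linearly along the apical-basal axis.

    ``fold`` is the designed pooled ratio between the basal third of the axis
    (transect bins 1-10 of 30) and the upper two thirds (bins 11-30), for
    cells of the home domain; ``direction`` is "basal" (high at the base) or
    "apical" (the mirrored profile, quoted as apex:base fold).
    """

    gene: str
    home_domain: str
    fold: float
    direction: str = "basal"


@dataclass(frozen=True)
class EctopicSpec:
    """Ectopic misexpression: extra uniform rate of ``gene`` in ``domains``,
    with the gene's axial gradient flattened (the misexpression genotype)."""

    gene: str
    rate: float
    domains: tuple[str, ...]


@dataclass
class SpikeSpec:
    """Full description of one synthetic sample."""

    stage: str = "W4"
    genotype: str = "P1WT"
    n_positions: int = 13
    cells_per_domain: dict[str, int] = field(default_factory=dict)
    domain_programs: pd.DataFrame | None = None  # domains × genes mean rates
    gradient_genes: list[GradientGene] = field(default_factory=list)
    ectopic: EctopicSpec | None = None
    blank_rate: float = 0.0028
    artifact_fraction: float = 0.05
    lowcount_fraction: float = 0.05
    lowcount_scale: float = 0.1
    mean_total_counts: float = 115.0
    size_factor_sigma: float = 0.35
    nb_dispersion: float | None = None  # optional Gamma-Poisson overdispersion
    seed: int = 0

    @property
    def sample_id(self) -> str:
        return f"{self.stage}_{self.genotype}"

    def __post_init__(self):
        if self.n_positions < 2:
            raise FormatError("n_positions must be >= 2")
        if not 0 <= self.blank_rate < 1:
            raise FormatError("blank_rate must be in [0, 1)")
        for frac in (self.artifact_fraction, self.lowcount_fraction):
            if not 0 <= frac <= 1:
                raise FormatError("fractions must be in [0, 1]")
        if not self.cells_per_domain:
            self.cells_per_domain = default_cells_per_domain(self.n_positions)
        if self.domain_programs is None:
            self.domain_programs = default_programs(sorted(self.cells_per_domain))
            if not self.gradient_genes:
                self.gradient_genes = default_gradient_genes()
        if (self.domain_programs.to_numpy() < 0).any():
            raise FormatError("program rates must be >= 0")

    def spec_hash(self) -> str:
        d = asdict(self)
        d["domain_programs"] = self.domain_programs.round(9).to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Ground truth for one generated sample."""

    cells: pd.DataFrame  # index cell_id: true_domain, group_id, position,
    #                      is_artifact, is_lowcount
    gradient: dict[str, dict]  # gene → effective axial parameters
    blank_rate: float
    designed_markers: dict[str, list[str]]  # domain → marker genes


# ---------------------------------------------------------------------------
# default study conditions


def default_cells_per_domain(n_positions: int = 13) -> dict[str, int]:
    prof = _lr_profile(n_positions)
    return {
        "rachis": 20 * n_positions,
        "vasculature": 10 * n_positions,
        "am": 24 * n_positions,
        "lr": int(sum(prof)),
    }


def _lr_profile(n_positions: int) -> list[int]:
    prof = list(LR_SIZE_PROFILE)
    if n_positions <= len(prof):
        return prof[:n_positions]
    return prof + [12] * (n_positions - len(prof))


def marker_genes(domain: str, n: int = 8) -> list[str]:
    prefix = {"rachis": "RCH", "vasculature": "VSC", "am": "AM", "lr": "LR"}.get(
        domain, domain.upper()[:3]
    )
    return [f"{prefix}-M{i}" for i in range(1, n + 1)]


def axial_genes(domain: str) -> list[str]:
    """Dedicated axially graded genes of a flank tissue (3 basal-high,
    3 apical-high), kept separate from the uniform domain markers."""
    prefix = {"am": "AMX", "lr": "LRX"}.get(domain, domain.upper()[:2] + "X")
    return [f"{prefix}-B{i}" for i in (1, 2, 3)] + [f"{prefix}-A{i}" for i in (1, 2, 3)]


def default_programs(domains) -> pd.DataFrame:
    """Mean expression rates (counts/cell) per domain.

    Each domain gets 8 strong uniform markers (7 counts/cell at home, 0.25
    elsewhere) and — for the AM and LR flank tissues — six moderate axially
    graded genes, plus a shared housekeeping block, the two reciprocal
    gradient genes VRT2 (rachis-restricted) and SEP1-4 (spikelet/AM-
    restricted) at rates giving ~30% detection in their home tissue, and a
    homoeolog cross-hybridization probe at 0.20 counts/cell everywhere.
    """
    domains = list(domains)
    hk = [f"HK-{i:02d}" for i in range(1, 21)]
    genes: list[str] = []
    for d in domains:
        genes += marker_genes(d)
    for d in ("am", "lr"):
        if d in domains:
            genes += axial_genes(d)
    genes += hk + ["VRT2", "SEP1-4", "BGENOME-PROBE"]
    prog = pd.DataFrame(0.0, index=domains, columns=genes)
    for d in domains:
        for g in marker_genes(d):
            prog.loc[:, g] = 0.25
            prog.loc[d, g] = 7.0
    for d in ("am", "lr"):
        if d in domains:
            for g in axial_genes(d):
                prog.loc[:, g] = 0.1
                prog.loc[d, g] = 0.8
    prog.loc[:, hk] = 2.5
    prog.loc[:, "VRT2"] = 0.03
    prog.loc[:, "SEP1-4"] = 0.03
    if "rachis" in domains:
        prog.loc["rachis", "VRT2"] = 1.2
    if "am" in domains:
        prog.loc["am", "SEP1-4"] = 1.2
    # set so the realized mean (after the global rescale and low-count cells)
    # lands at ~0.20 detected transcripts per cell
    prog.loc[:, "BGENOME-PROBE"] = 0.22
    return prog


def default_gradient_genes() -> list[GradientGene]:
    out = [
        GradientGene("VRT2", "rachis", 3.46, "basal"),
        GradientGene("SEP1-4", "am", 3.46, "apical"),
    ]
    for d in ("am", "lr"):
        for g in axial_genes(d):
            direction = "basal" if "-B" in g else "apical"
            out.append(GradientGene(g, d, 2.0, direction))
    return out


def axial_program_spec(
    stage: str = "W2.5", genotype: str = "P1WT", seed: int = 0
) -> SpikeSpec:
    """A spike with a strong designed monotone axial program in the flank
    tissues: the dedicated axial genes are raised to rates and folds at which
    the group-averaged profiles dominate PC1, for axis-recovery tests."""
    spec = default_spec(stage, genotype, seed=seed)
    prog = spec.domain_programs.copy()
    for d in ("am", "lr"):
        for g in axial_genes(d):
            prog.loc[d, g] = 4.0
    spec.domain_programs = prog
    spec.gradient_genes = [
        gg if gg.gene in ("VRT2", "SEP1-4") else GradientGene(gg.gene, gg.home_domain, 3.0, gg.direction)
        for gg in spec.gradient_genes
    ]
    return spec


def default_spec(stage: str = "W4", genotype: str = "P1WT", seed: int = 0) -> SpikeSpec:
    """The default study conditions for one sample; the misexpression
    genotype adds ectopic VRT2 in spikelet domains and flattens its basal
    gradient."""
    ectopic = None
    if genotype == "P1POL":
        ectopic = EctopicSpec("VRT2", rate=1.0, domains=("am", "lr"))
    return SpikeSpec(stage=stage, genotype=genotype, ectopic=ectopic, seed=seed)


def default_bundle(base_seed: int = 0) -> list[SpikeSpec]:
    """The 8-sample study design: 4 stages × 2 genotypes."""
    specs = []
    i = 0
    for stage in _io.STAGES:
        for genotype in _io.GENOTYPES:
            specs.append(default_spec(stage, genotype, seed=(base_seed * 1000 + i) % 2**31))
            i += 1
    return specs


# ---------------------------------------------------------------------------
# gradient calibration


def pooled_ratio(k: float) -> float:
    """Expected basal-third : upper-two-thirds pooled mean ratio of
    exp(-k t) over t uniform on [0, 1]."""
    if abs(k) < 1e-12:
        return 1.0
    return 2.0 * (1.0 - np.exp(-k / 3.0)) / (np.exp(-k / 3.0) - np.exp(-k))


def slope_for_fold(fold: float) -> float:
    """Log-linear slope k whose pooled basal:upper ratio equals ``fold``."""
    if fold <= 0:
        raise FormatError("gradient fold must be > 0")
    if abs(fold - 1.0) < 1e-12:
        return 0.0
    if fold < 1:
        return -slope_for_fold(1.0 / fold)
    return brentq(lambda k: pooled_ratio(k) - fold, 1e-9, 60.0)


def gradient_weight(t: np.ndarray, k: float, direction: str) -> np.ndarray:
    """Axial weight with unit mean over t ~ U[0,1]; t=0 is the spike base."""
    if abs(k) < 1e-12:
        return np.ones_like(t)
    u = t if direction == "basal" else 1.0 - t
    norm = k / (1.0 - np.exp(-k))  # so the mean over u∈[0,1] is 1
    return norm * np.exp(-k * u)


def _calibrate_slope(
    t: np.ndarray,
    home: np.ndarray,
    base_rate: float,
    other_rates: np.ndarray,
    fold: float,
    direction: str,
) -> float:
    """Solve the log-linear slope so the designed fold is the *realized*
    pooled transect ratio.

    The pooled basal (bins 1-10) vs upper (bins 11-30) per-cell mean includes
    cells of every domain, so baseline expression and any non-uniform axial
    composition (basal leaf ridges are larger) dilute the home-domain
    gradient; the slope is therefore solved against the actual cell layout
    rather than the uniform-density closed form.  For apical-direction genes
    the mirrored statistic (upper third vs lower two thirds) is used.
    """
    if abs(fold - 1.0) < 1e-12:
        return 0.0
    enriched = t <= 1.0 / 3.0 if direction == "basal" else t >= 2.0 / 3.0

    def realized(k: float) -> float:
        lam = other_rates.astype(float).copy()
        lam[home] = base_rate * gradient_weight(t[home], k, direction)
        return lam[enriched].mean() / lam[~enriched].mean()

    lo, hi = 1e-9, 80.0
    if not (realized(lo) < fold < realized(hi)):
        return slope_for_fold(fold)  # fall back to the uniform-density form
    return brentq(lambda k: realized(k) - fold, lo, hi)


# ---------------------------------------------------------------------------
# layout


def _apportion(total: int, n_parts: int) -> list[int]:
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def _square(cx: float, cy: float, side: float) -> Polygon:
    h = side / 2.0
    return box(cx - h, cy - h, cx + h, cy + h)


def build_spike_layout(spec: SpikeSpec, seed: int | None = None):
    """Lay out the synthetic spike as non-overlapping convex cell tiles.

    Returns ``(polygons, cells, truth)``: the ``cell_id → Polygon`` map, the
    cell metadata table (centres, volumes, sample annotations) and the
    :class:`SyntheticTruth`.
    """
    if sum(spec.cells_per_domain.values()) <= 0:
        raise FormatError("cells_per_domain totals must be > 0")
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_layout, _ = [np.random.default_rng(s) for s in ss.spawn(2)]

    n_pos = spec.n_positions
    rows_per_band = int(BAND_HEIGHT // CELL_SIDE)
    nP = spec.cells_per_domain
    vasc_pp = _apportion(nP.get("vasculature", 0), n_pos)
    rach_pp = _apportion(nP.get("rachis", 0), n_pos)
    am_pp = _apportion(nP.get("am", 0), n_pos)
    lr_total = nP.get("lr", 0)
    prof = np.array(_lr_profile(n_pos), dtype=float)
    lr_pp = np.floor(prof * lr_total / prof.sum()).astype(int)
    for i in np.argsort(-(prof * lr_total / prof.sum() - lr_pp))[: lr_total - lr_pp.sum()]:
        lr_pp[i] += 1

    polygons: dict[str, Polygon] = {}
    rows = []
    counter = 0

    def add_cell(cx, cy, side, domain, group_id, position):
        nonlocal counter
        cid = f"{spec.sample_id}-c{counter:05d}"
        counter += 1
        polygons[cid] = _square(cx, cy, side)
        rows.append((cid, domain, group_id, position))

    def central_slots():
        # inner columns first: x centres ±5, ±15, ±25, ...
        i = 0
        while True:
            off = CELL_SIDE / 2 + (i // 2) * CELL_SIDE
            yield -off if i % 2 == 0 else off
            i += 1

    max_flank_edge = 0.0
    max_central_edge = 0.0
    for p in range(1, n_pos + 1):
        y0 = (p - 1) * BAND_HEIGHT
        ys = [y0 + CELL_SIDE / 2 + r * CELL_SIDE for r in range(rows_per_band)]
        side = -1.0 if p % 2 == 1 else 1.0  # flank alternates by position

        # central tissue: vasculature innermost, rachis continuing outward
        cols = central_slots()
        central_edge = 0.0
        for domain, n in (("vasculature", vasc_pp[p - 1]), ("rachis", rach_pp[p - 1])):
            placed = 0
            while placed < n:
                x = next(cols)
                central_edge = max(central_edge, abs(x) + CELL_SIDE / 2)
                for y in ys:
                    if placed >= n:
                        break
                    add_cell(x, y, CELL_SIDE, domain, "", 0)
                    placed += 1

        # AM block then adjacent LR block on the flank, one cell-gap apart
        x_edge = central_edge + CELL_SIDE  # gap between rachis and flank
        for domain, n, label in (
            ("am", am_pp[p - 1], f"AM-{p:02d}"),
            ("lr", int(lr_pp[p - 1]), f"LR-{p:02d}"),
        ):
            placed = 0
            col = 0
            while placed < n:
                x = side * (x_edge + CELL_SIDE / 2 + col * CELL_SIDE)
                for y in ys:
                    if placed >= n:
                        break
                    add_cell(x, y, CELL_SIDE, domain, label, p)
                    placed += 1
                col += 1
            x_edge += col * CELL_SIDE + CELL_SIDE  # gap before next block
        max_flank_edge = max(max_flank_edge, x_edge)
        max_central_edge = max(max_central_edge, central_edge)

    n_real = counter
    # artifacts: tiny tiles on each position's empty flank
    f = spec.artifact_fraction
    n_art = int(rng_layout.binomial(n_real, f / (1.0 - f))) if f > 0 else 0
    slots = []
    x_lo = max_central_edge + CELL_SIDE  # clear of the widest central column
    x_hi = max(max_flank_edge, x_lo + 100.0)
    xs = np.arange(x_lo, x_hi, 8.0)
    for p in range(1, n_pos + 1):
        empty_side = 1.0 if p % 2 == 1 else -1.0
        y0 = (p - 1) * BAND_HEIGHT
        for x in xs:
            for y in np.arange(y0 + 4.0, y0 + BAND_HEIGHT - 3.0, 8.0):
                slots.append((empty_side * x, y))
    if n_art > len(slots):
        raise FormatError("too many artifacts for available layout space")
    for i in rng_layout.choice(len(slots), size=n_art, replace=False):
        cx, cy = slots[i]
        add_cell(cx, cy, ARTIFACT_SIDE, "artifact", "", 0)

    truth_cells = pd.DataFrame(
        rows, columns=["cell_id", "true_domain", "group_id", "position"]
    ).set_index("cell_id")
    truth_cells["is_artifact"] = truth_cells["true_domain"] == "artifact"
    real_ids = truth_cells.index[~truth_cells["is_artifact"]]
    lowcount = np.zeros(len(truth_cells), dtype=bool)
    n_low = int(rng_layout.binomial(len(real_ids), spec.lowcount_fraction))
    pick = rng_layout.choice(len(real_ids), size=n_low, replace=False)
    lowcount[truth_cells.index.get_indexer(real_ids[pick])] = True
    truth_cells["is_lowcount"] = lowcount

    from .geometry import derive_cell_metadata

    cells = derive_cell_metadata(polygons, section_thickness=10.0)
    cells = cells.loc[truth_cells.index]
    cells["sample_id"] = spec.sample_id
    cells["stage"] = spec.stage
    cells["genotype"] = spec.genotype

    # calibrate gradient slopes against the realized composition of cells
    # that survive QC (artifacts and low-count cells are filtered out
    # before any transect analysis)
    valid = (~truth_cells["is_artifact"] & ~truth_cells["is_lowcount"]).to_numpy()
    yv = cells["center_y"].to_numpy(float)
    y_lo, y_hi = yv[~truth_cells["is_artifact"].to_numpy()].min(), yv.max()
    t_all = np.clip((yv - y_lo) / max(y_hi - y_lo, 1e-12), 0.0, 1.0)
    dom_all = truth_cells["true_domain"].to_numpy()
    prog = spec.domain_programs
    gradient = {}
    for gg in spec.gradient_genes:
        fold = gg.fold
        if spec.ectopic is not None and spec.ectopic.gene == gg.gene:
            fold = 1.0  # misexpression flattens the axial gradient
        base_rate = float(prog.loc[gg.home_domain, gg.gene])
        other = np.array(
            [
                prog.loc[d, gg.gene] if d != "artifact" else 0.0
                for d in dom_all[valid]
            ]
        )
        if spec.ectopic is not None and spec.ectopic.gene == gg.gene:
            other = other + np.where(
                np.isin(dom_all[valid], spec.ectopic.domains), spec.ectopic.rate, 0.0
            )
        home = dom_all[valid] == gg.home_domain
        gradient[gg.gene] = {
            "home_domain": gg.home_domain,
            "fold": fold,
            "direction": gg.direction,
            "slope": _calibrate_slope(t_all[valid], home, base_rate, other, fold, gg.direction),
            "y_range": [float(y_lo), float(y_hi)],
        }
    truth = SyntheticTruth(
        cells=truth_cells,
        gradient=gradient,
        blank_rate=spec.blank_rate,
        designed_markers={
            d: [g for g in marker_genes(d) if g in spec.domain_programs.columns]
            for d in spec.cells_per_domain
        },
    )
    return polygons, cells, truth


# ---------------------------------------------------------------------------
# counts


def _rate_matrix(cells: pd.DataFrame, truth: SyntheticTruth, spec: SpikeSpec):
    """Expected counts per cell × gene before the size factor."""
    prog = spec.domain_programs
    genes = list(prog.columns)
    domains = truth.cells["true_domain"].to_numpy()
    # artifacts express a faint average program
    art_row = prog.mean(axis=0).to_numpy() * 0.08
    rates = np.empty((len(cells), len(genes)))
    for i, d in enumerate(domains):
        rates[i] = art_row if d == "artifact" else prog.loc[d].to_numpy()

    y = cells["center_y"].to_numpy(float)
    real = ~truth.cells["is_artifact"].to_numpy()
    y_lo, y_hi = y[real].min(), y[real].max()
    span = max(y_hi - y_lo, 1e-12)
    t = np.clip((y - y_lo) / span, 0.0, 1.0)
    gi = {g: j for j, g in enumerate(genes)}
    for gene, par in truth.gradient.items():
        if gene not in gi:
            continue
        mask = domains == par["home_domain"]
        w = gradient_weight(t[mask], par["slope"], par["direction"])
        rates[mask, gi[gene]] *= w
    if spec.ectopic is not None and spec.ectopic.gene in gi:
        mask = np.isin(domains, spec.ectopic.domains)
        rates[mask, gi[spec.ectopic.gene]] += spec.ectopic.rate

    # rescale so the expected mean total over normal cells hits the target
    normal = (~truth.cells["is_artifact"] & ~truth.cells["is_lowcount"]).to_numpy()
    expected = rates[normal].sum(axis=1).mean()
    rates *= spec.mean_total_counts / expected
    return rates, genes


def sample_counts(
    polygons: dict[str, Polygon],
    cells: pd.DataFrame,
    truth: SyntheticTruth,
    spec: SpikeSpec,
    seed: int | None = None,
    emit_transcripts: bool = True,
):
    """Draw the count matrix (and transcript point cloud) for a laid-out spike.

    Counts are Poisson (optionally Gamma-Poisson when ``nb_dispersion`` is
    set) with per-cell lognormal size factors; blanks are drawn so the
    expected blank fraction of all detections equals ``spec.blank_rate``;
    each counted transcript is also emitted at a uniform point inside its
    cell tile when ``emit_transcripts``.
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    _, rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    rates, genes = _rate_matrix(cells, truth, spec)
    n = len(cells)
    sigma = spec.size_factor_sigma
    size = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    size[truth.cells["is_lowcount"].to_numpy()] *= spec.lowcount_scale
    lam = rates * size[:, None]
    if spec.nb_dispersion:
        shape = 1.0 / spec.nb_dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    X = rng.poisson(lam).astype(float)

    blank_names = [f"Blank-{i}" for i in range(1, N_BLANKS + 1)]
    br = spec.blank_rate
    lam_blank = lam.sum(axis=1) * (br / (1.0 - br)) / N_BLANKS if br > 0 else np.zeros(n)
    B = rng.poisson(np.repeat(lam_blank[:, None], N_BLANKS, axis=1)).astype(float)

    all_genes = genes + blank_names
    adata = _io.counts_from_arrays(np.hstack([X, B]), cells.index, all_genes)

    transcripts = None
    if emit_transcripts:
        full = np.hstack([X, B]).astype(int)
        rows, cols = np.nonzero(full)
        counts = full[rows, cols]
        r_idx = np.repeat(rows, counts)
        g_idx = np.repeat(cols, counts)
        eps = 1e-3
        bounds = np.array([polygons[c].bounds for c in cells.index])
        lo = bounds[r_idx, :2] + eps
        hi = bounds[r_idx, 2:] - eps
        pts = lo + rng.random((len(r_idx), 2)) * (hi - lo)
        transcripts = pd.DataFrame(
            {
                "gene": np.array(all_genes, dtype=object)[g_idx],
                "global_x": pts[:, 0],
                "global_y": pts[:, 1],
                "cell_id": cells.index.to_numpy()[r_idx],
            }
        )
        # deterministic presentation order
        transcripts = transcripts.sort_values(
            ["cell_id", "gene", "global_x"], kind="stable"
        ).reset_index(drop=True)
    return adata, transcripts


def synthetic_bulk_reference(
    spec: SpikeSpec, seed: int | None = None, noise_sigma: float = 0.7
) -> pd.Series:
    """A pseudo-TPM bulk reference for the sample's stage-section-genotype.

    Expected per-gene abundance under the spec's domain mixture, perturbed by
    lognormal noise emulating platform and sectioning differences between
    imaging-based counts and bulk RNA-seq, then scaled to TPM (sum 1e6).
    The default noise level puts the rank concordance between an in-silico
    dissection and this reference in the mid-0.6 range typical of
    imaging-panel versus bulk comparisons.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed + 7919) % 2**31))
    weights = pd.Series(spec.cells_per_domain, dtype=float)
    weights /= weights.sum()
    mean_rates = spec.domain_programs.mul(weights, axis=0).sum(axis=0)
    noisy = mean_rates * np.exp(rng.normal(0.0, noise_sigma, size=len(mean_rates)))
    return (noisy / noisy.sum() * 1e6).rename("tpm")


# ---------------------------------------------------------------------------
# dataset bundles on disk


def truth_to_groups(truth: SyntheticTruth) -> pd.DataFrame:
    g = truth.cells.loc[truth.cells["group_id"] != ""].reset_index()
    g["tissue_class"] = g["group_id"].str.split("-").str[0]
    return g[["group_id", "tissue_class", "position", "cell_id"]]


def generate_dataset(
    specs: list[SpikeSpec], out_dir: str | Path, emit_transcripts: bool = True
) -> Path:
    """Write a full multi-sample dataset bundle to ``out_dir``.

    One directory per sample with the complete file set (cells, counts,
    transcripts, polygons, ROI, groups, truth, bulk reference) plus a
    top-level ``manifest.json`` recording seeds and spec hashes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in spec list")
    manifest = {"samples": {}}
    for spec in specs:
        polygons, cells, truth = build_spike_layout(spec)
        adata, transcripts = sample_counts(
            polygons, cells, truth, spec, emit_transcripts=emit_transcripts
        )
        d = out_dir / spec.sample_id
        d.mkdir(exist_ok=True)
        _io.write_cell_metadata(cells, d / "cells.csv")
        _io.write_count_matrix(adata, d / "counts.csv")
        _io.write_polygons(polygons, d / "polygons.geojson")
        if transcripts is not None:
            _io.write_transcripts(transcripts, d / "transcripts.csv")
        real = cells.loc[~truth.cells["is_artifact"]]
        margin = 2.0
        roi = _io.RoiPolygon(
            "inflorescence",
            box(
                real["center_x"].min() - margin,
                real["center_y"].min() - margin,
                real["center_x"].max() + margin,
                real["center_y"].max() + margin,
            ),
        )
        _io.write_rois([roi], d / "roi.geojson")
        _io.write_groups(truth_to_groups(truth), d / "groups.csv")
        truth.cells.to_csv(d / "truth.csv", index_label="cell_id")
        _io.write_bulk_reference(synthetic_bulk_reference(spec), d / "bulk_reference.csv")
        with open(d / "truth.json", "w") as fh:
            json.dump(
                {
                    "gradient": truth.gradient,
                    "blank_rate": truth.blank_rate,
                    "designed_markers": truth.designed_markers,
                },
                fh,
                indent=1,
            )
        manifest["samples"][spec.sample_id] = {
            "seed": spec.seed,
            "spec_hash": spec.spec_hash(),
            "n_cells": int(len(cells)),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir


def read_truth(sample_dir: str | Path) -> SyntheticTruth:
    """Read back the ground truth written by :func:`generate_dataset`."""
    sample_dir = Path(sample_dir)
    cells = pd.read_csv(sample_dir / "truth.csv", index_col="cell_id")
    cells.index = cells.index.astype(str)
    cells["group_id"] = cells["group_id"].fillna("")
    with open(sample_dir / "truth.json") as fh:
        meta = json.load(fh)
    return SyntheticTruth(
        cells=cells,
        gradient=meta["gradient"],
        blank_rate=meta["blank_rate"],
        designed_markers=meta["designed_markers"],
    )
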