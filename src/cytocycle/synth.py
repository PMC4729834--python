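"""Synthetic imaging-flow-cytometry populations with known cell-cycle state.

Generates paired brightfield/darkfield (and optionally nuclear-stain)
single-cell images whose statistics mirror what the label-free workflow
assumes about real data:

* DNA content ``c`` runs from 2N in G1 through S (linear in cycle position)
  to 4N in G2 and all mitotic phases.
* Cell size couples to DNA content through a power law, so bigger cells
  carry more DNA.
* Mitotic phases are rare and morphologically distinct (condensed-texture
  prophase, elongated metaphase plate, overlapping anaphase lobes,
  disjoint telophase daughters).
* The darkfield channel is a speckle field whose integrated intensity
  scales with ``c`` but whose spatial layout is deliberately *not*
  registered with the brightfield cell.
* The stain channel is stoichiometric: integrated intensity equals
  ``c * dna_g1`` up to multiplicative noise of coefficient-of-variation
  ``stain_cv``.

All morphology rules are synthetic stand-ins for real microscopy; they are
meant to exercise the analysis pipeline, not to model optics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "INTERPHASE",
    "MITOTIC",
    "PopulationConfig",
    "CellState",
    "CellRecord",
    "sample_cell_state",
    "render_cell",
    "generate_population",
    "write_population",
    "read_population",
]

#: canonical phase order (interphase first, then mitosis in temporal order)
PHASES = ("G1", "S", "G2", "prophase", "metaphase", "anaphase", "telophase")
INTERPHASE = ("G1", "S", "G2")
MITOTIC = ("prophase", "metaphase", "anaphase", "telophase")

#: default phase priors: heavy interphase, mitotic classes jointly ~5%
DEFAULT_PRIORS = {
    "G1": 0.55,
    "S": 0.20,
    "G2": 0.20,
    "prophase": 0.02,
    "metaphase": 0.01,
    "anaphase": 0.01,
    "telophase": 0.01,
}


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a synthetic cell population.

    Attributes
    ----------
    n_cells : int
        Number of cells to generate.
    phase_priors : dict
        Probability of each phase in :data:`PHASES`; must sum to 1.
    dna_g1 : float
        Integrated stain intensity of a 2N (G1) cell, arbitrary units.
    stain_cv : float
        Coefficient of variation of the multiplicative stain noise.
    size_coupling : float
        Exponent linking nominal cell radius to DNA content,
        ``radius = base_radius * (c/2)**size_coupling``.
    noise_sd : float
        Additive Gaussian pixel noise (gray levels, images live in [0, 1]).
    image_side_range : (int, int)
        Min/max image side in pixels; each cell draws its side uniformly.
    block_shift : float
        Probability mass moved from G1/S into the G2 + mitotic pool,
        emulating a mitotic blocking agent (0 = untreated).
    seed : int
        Population RNG seed; per-cell streams are derived from it.
    base_radius : float
        Nominal radius (px) of a 2N cell before jitter.
    radius_jitter : float
        Log-normal sigma of the per-cell radius jitter.
    df_gain : float
        Integrated darkfield intensity per unit DNA content.
    with_stain : bool
        Whether to render the stain channel.
    """

    n_cells: int = 1000
    phase_priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    dna_g1: float = 20.0
    stain_cv: float = 0.05
    size_coupling: float = 0.33
    noise_sd: float = 0.05
    image_side_range: tuple = (30, 60)
    block_shift: float = 0.0
    seed: int = 0
    base_radius: float = 9.0
    radius_jitter: float = 0.08
    df_gain: float = 10.0
    with_stain: bool = True

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if set(self.phase_priors) != set(PHASES):
            raise ValueError(f"phase_priors must cover exactly {PHASES}")
        total = sum(self.phase_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase_priors must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.phase_priors.values()):
            raise ValueError("phase_priors must be non-negative")
        if not (0.0 <= self.stain_cv < 0.5):
            raise ValueError("stain_cv must lie in [0, 0.5)")
        lo, hi = self.image_side_range
        if not (20 <= lo <= hi <= 128):
            raise ValueError("image_side_range must satisfy 20 <= min <= max <= 128")
        interphase_g1s = self.phase_priors["G1"] + self.phase_priors["S"]
        if not (0.0 <= self.block_shift <= interphase_g1s):
            raise ValueError("block_shift must be in [0, P(G1)+P(S)]")

    def effective_priors(self) -> dict:
        """Phase priors after applying the mitotic-block shift.

        Mass ``block_shift`` is removed from G1 and S (proportionally to
        their priors) and added to G2 plus the mitotic classes
        (proportionally to theirs), emulating accumulation at the block.
        """
        p = dict(self.phase_priors)
        s = self.block_shift
        if s == 0:
            return p
        donors = ("G1", "S")
        acceptors = ("G2",) + MITOTIC
        donor_mass = sum(p[k] for k in donors)
        acceptor_mass = sum(p[k] for k in acceptors)
        for k in donors:
            p[k] -= s * p[k] / donor_mass
        if acceptor_mass > 0:
            for k in acceptors:
                p[k] += s * p[k] / acceptor_mass
        else:  # degenerate: no acceptor mass to scale, put it all in G2
            p["G2"] += s
        return p


@dataclass(frozen=True)
class CellState:
    """Ground-truth state of one cell."""

    phase: str
    cycle_position: float  # fraction in [0, 1) within interphase
    dna_content: float  # unitless, 2 (2N) .. 4 (4N)
    nominal_radius: float  # px

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not (2.0 <= self.dna_content <= 4.0):
            raise ValueError("dna_content must lie in [2, 4]")
        if self.nominal_radius <= 0:
            raise ValueError("nominal_radius must be positive")


@dataclass
class CellRecord:
    """One cell's images plus identifiers and (optional) ground truth."""

    cell_id: str
    brightfield: np.ndarray
    darkfield: np.ndarray
    stain: Optional[np.ndarray] = None
    truth: Optional[CellState] = None

    def __post_init__(self):
        if self.brightfield.shape != self.darkfield.shape:
            raise ValueError("brightfield and darkfield must share dimensions")
        for name in ("brightfield", "darkfield", "stain"):
            img = getattr(self, name)
            if img is None:
                continue
            if not np.all(np.isfinite(img)) or np.any(img < 0):
                raise ValueError(f"{name} pixels must be finite and >= 0")


def _dna_content(phase: str, t: float) -> float:
    if phase == "G1":
        return 2.0
    if phase == "S":
        return 2.0 + 2.0 * t  # linear replication through S
    return 4.0  # G2 and all mitotic phases


def sample_cell_state(config: PopulationConfig, rng: np.random.Generator) -> CellState:
    """Draw one cell's phase, cycle position, DNA content and radius."""
    priors = config.effective_priors()
    probs = np.array([priors[ph] for ph in PHASES])
    phase = PHASES[rng.choice(len(PHASES), p=probs / probs.sum())]
    t = float(rng.uniform(0.0, 1.0))
    c = _dna_content(phase, t)
    radius = (
        config.base_radius
        * (c / 2.0) ** config.size_coupling
        * float(np.exp(rng.normal(0.0, config.radius_jitter)))
    )
    return CellState(phase=phase, cycle_position=t, dna_content=c, nominal_radius=radius)


def _disk(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _draw_shape_params(state: CellState, rng: np.random.Generator) -> dict:
    """Per-cell shape parameters; the jitter emulates biological variability.

    Interphase cells are mildly elliptical; the metaphase plate is strongly
    elongated (axis ratio >= 1.6); anaphase renders as two overlapping
    lobes, telophase as two disjoint ones; prophase is a slightly smaller
    cell with condensed-chromatin texture of variable strength.
    """
    p = {"phase": state.phase, "theta": rng.uniform(0, np.pi)}
    if state.phase == "metaphase":
        p["ratio"] = rng.uniform(1.6, 2.4)
    elif state.phase == "anaphase":
        p["lobe_frac"] = rng.uniform(0.70, 0.80)
        p["sep"] = rng.uniform(1.0, 1.6)
    elif state.phase == "telophase":
        p["lobe_frac"] = rng.uniform(0.65, 0.75)
        p["sep"] = rng.uniform(2.8, 3.6)
    elif state.phase == "prophase":
        p["shrink"] = rng.uniform(0.80, 1.00)
        p["ratio"] = rng.uniform(1.0, 1.3)
        p["texture"] = rng.uniform(0.06, 0.20)
    else:  # interphase: mildly elliptical
        p["ratio"] = rng.uniform(1.0, 1.4)
    return p


def _phase_extent(state: CellState, shape: dict) -> float:
    """Largest object diameter (px) implied by the drawn geometry."""
    r = state.nominal_radius
    phase = state.phase
    if phase in ("anaphase", "telophase"):
        rl = shape["lobe_frac"] * r
        return 2 * rl + shape["sep"] * rl
    if phase == "prophase":
        return 2 * r * shape["shrink"] * np.sqrt(shape["ratio"])
    return 2 * r * np.sqrt(shape["ratio"])


def render_cell(
    state: CellState,
    config: PopulationConfig,
    rng: np.random.Generator,
    cell_id: str = "cell",
) -> CellRecord:
    """Render one cell's brightfield/darkfield (+ stain) images.

    Brightfield: bright interior with a darker 2-px rim on a mid-gray
    background. Darkfield: gamma speckle in an off-centre blob, scaled so
    its integrated intensity equals ``df_gain * c`` up to 10% noise.
    Stain: uniform disk with integral ``c * dna_g1 * (1 + eps)``,
    ``eps ~ N(0, stain_cv)``.
    """
    shape = _draw_shape_params(state, rng)
    extent = _phase_extent(state, shape)
    lo, hi = config.image_side_range
    min_side = int(np.ceil(extent)) + 4
    if min_side > hi:
        raise ValueError(
            f"cell extent {extent:.1f}px does not fit the maximum image side {hi}"
        )
    side = int(rng.integers(max(lo, min_side), hi + 1))
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    r = state.nominal_radius

    def _ellipse_masks(radius, ratio, theta):
        a, b = radius * np.sqrt(ratio), radius / np.sqrt(ratio)
        yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        outer = (yr / a) ** 2 + (xr / b) ** 2 <= 1.0
        inner = (yr / max(a - 2, 1)) ** 2 + (xr / max(b - 2, 1)) ** 2 <= 1.0
        return outer, inner

    # --- object geometry: `outer` is the cell outline at nominal_radius,
    # the rim (membrane) is its outermost 2 px
    phase = state.phase
    if phase in ("anaphase", "telophase"):
        rl = shape["lobe_frac"] * r
        dy = np.sin(shape["theta"]) * shape["sep"] * rl / 2
        dx = np.cos(shape["theta"]) * shape["sep"] * rl / 2
        outer = _disk(yy, xx, cy - dy, cx - dx, rl) | _disk(yy, xx, cy + dy, cx + dx, rl)
        interior = _disk(yy, xx, cy - dy, cx - dx, max(rl - 2, 1)) | _disk(
            yy, xx, cy + dy, cx + dx, max(rl - 2, 1)
        )
    elif phase == "prophase":
        outer, interior = _ellipse_masks(r * shape["shrink"], shape["ratio"], shape["theta"])
    else:
        outer, interior = _ellipse_masks(r, shape["ratio"], shape["theta"])
    rim = outer & ~interior

    # --- brightfield ----------------------------------------------------
    bf = np.full((side, side), 0.5)
    bf[interior] = 0.75
    bf[rim] = 0.25
    if phase == "prophase":
        # condensed chromatin: high-frequency interior texture of
        # cell-dependent strength
        tex = rng.normal(0.0, shape["texture"], size=(side, side))
        bf[interior] += tex[interior]
    if config.noise_sd > 0:
        bf += rng.normal(0.0, config.noise_sd, size=(side, side))
    bf = np.clip(bf, 0.0, 1.0)

    # --- darkfield: speckle, not registered with the brightfield --------
    off = rng.uniform(-0.15 * side, 0.15 * side, size=2)
    blob = _disk(yy, xx, cy + off[0], cx + off[1], 1.1 * r)
    speckle = rng.gamma(2.0, 1.0, size=(side, side)) * (0.15 + blob)
    target = config.df_gain * state.dna_content * (1.0 + rng.normal(0.0, 0.10))
    speckle *= max(target, 1e-9) / speckle.sum()
    df = np.clip(speckle, 0.0, 1.0)

    # --- stain: stoichiometric disk -------------------------------------
    stain = None
    if config.with_stain:
        sr = max(0.6 * r, 2.0)
        sdisk = _disk(yy, xx, cy, cx, sr)
        eps = float(np.clip(rng.normal(0.0, config.stain_cv), -0.9, None))
        total = state.dna_content * config.dna_g1 * (1.0 + eps)
        stain = np.zeros((side, side))
        stain[sdisk] = total / sdisk.sum()
        stain = np.clip(stain, 0.0, 1.0)

    return CellRecord(
        cell_id=cell_id, brightfield=bf, darkfield=df, stain=stain, truth=state
    )


def generate_population(config: PopulationConfig):
    """Generate ``config.n_cells`` cells plus a ground-truth table.

    Each cell gets its own RNG stream derived from ``(seed, cell index)``
    through a :class:`numpy.random.SeedSequence`, so populations are
    bit-reproducible and individual cells are reproducible under
    subsetting.

    Returns
    -------
    (list of CellRecord, pandas.DataFrame)
        The truth table has columns ``cell_id, phase, dna_content,
        stain_integrated`` (NaN when no stain channel was rendered).
    """
    records = []
    rows = []
    width = max(4, len(str(config.n_cells - 1)))
    for i in range(config.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        state = sample_cell_state(config, rng)
        cell_id = f"c{i:0{width}d}"
        rec = render_cell(state, config, rng, cell_id=cell_id)
        records.append(rec)
        rows.append(
            {
                "cell_id": cell_id,
                "phase": state.phase,
                "dna_content": state.dna_content,
                "stain_integrated": float(rec.stain.sum()) if rec.stain is not None else np.nan,
            }
        )
    truth = pd.DataFrame(rows)
    return records, truth


def write_population(records, truth: pd.DataFrame, outdir) -> None:
    """Write per-cell 16-bit TIFFs (`<cell_id>_<bf|df|stain>.tif`) + truth CSV."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        for channel, img in (
            ("bf", rec.brightfield),
            ("df", rec.darkfield),
            ("stain", rec.stain),
        ):
            if img is None:
                continue
            data = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
            tifffile.imwrite(outdir / f"{rec.cell_id}_{channel}.tif", data)
    truth.to_csv(outdir / "truth.csv", index=False, quoting=csv.QUOTE_MINIMAL)


def read_population(indir):
    """Read a population written by :func:`write_population`.

    Images come back as float arrays in [0, 1]; ground-truth states are not
    reconstructed (only the truth table carries them).
    """
    import tifffile

    indir = Path(indir)
    truth = pd.read_csv(indir / "truth.csv")
    records = []
    for cell_id in truth["cell_id"]:
        imgs = {}
        for channel in ("bf", "df", "stain"):
            path = indir / f"{cell_id}_{channel}.tif"
            imgs[channel] = (
                tifffile.imread(path).astype(float) / 65535.0 if path.exists() else None
            )
        records.append(
            CellRecord(
                cell_id=str(cell_id),
                brightfield=imgs["bf"],
                darkfield=imgs["df"],
                stain=imgs["stain"],
            )
        )
    return records, truth
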