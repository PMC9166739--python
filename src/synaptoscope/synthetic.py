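"""Ground-truthed synthetic data generators.

Three generators emulate the statistical structure the analysis assumes,
so every downstream stage can be exercised against a known truth:

* :func:`make_scene` renders sparse sub-resolution particles as isotropic
  2-D Gaussian spots on a noisy background, in two channels, with
  controlled fractions of single-positive (``A_only``, ``B_only``) and
  double-positive (``AB``) particles.  ``AB`` particles carry a
  channel-to-channel centroid offset drawn from a configurable law, which
  is what the centre-to-centre distance profiling downstream measures.
* :func:`make_point_sets` builds a pair of planar point sets with a
  planted fraction of associated pairs at a fixed offset, the remainder
  being complete-spatial-randomness (CSR) uniform — the fixture for the
  Monte-Carlo association test.
* :func:`make_peptide_table` builds a six-sample (3 control "SYN" + 3
  sorted "FASS" replicates) peptide-level intensity table with a constant
  background population plus planted enriched/depleted proteins, for the
  label-free proteome screen.

All randomness flows from one explicit seed per generator; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .association import PointSet
from .frames import ImageFrame

__all__ = [
    "SceneSpec",
    "GroundTruthParticle",
    "PeptideSpec",
    "make_scene",
    "make_point_sets",
    "make_peptide_table",
    "ground_truth_frame",
    "write_scene",
    "write_ground_truth",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered two-channel scene.

    Defaults emulate wide-field imaging of immobilized synaptosomes:
    ~0.1 um/px sampling, a PSF of sigma 1.5 px (~350 nm FWHM, consistent
    with particles of roughly 0.5 um), lognormal spot intensities
    (fluorescence is multiplicative) and additive Gaussian camera noise.

    ``counts`` gives the number of particles per class: ``A_only`` and
    ``B_only`` appear in a single channel, ``AB`` in both with a
    channel-to-channel offset of ``offset_um = (mean, sd)`` micrometres.
    Positions are uniform over the field excluding ``margin_px``; a
    positive ``min_separation_px`` enforces inter-particle spacing by
    dart throwing.
    """

    field_px: tuple[int, int] = (512, 512)  # (height, width)
    pixel_size_um: float = 0.1
    counts: dict[str, int] = field(
        default_factory=lambda: {"A_only": 5, "B_only": 5, "AB": 5}
    )
    offset_um: tuple[float, float] = (0.3, 0.05)  # mean, SD of AB offset
    intensity_law: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (8.5, 0.3), "B": (8.5, 0.3)}
    )  # natural-log mean / SD of total spot intensity (a.u.)
    psf_sigma_px: float = 1.5
    background: tuple[float, float] = (100.0, 5.0)  # mean level, noise SD
    margin_px: int = 30
    min_separation_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.background[1] < 0:
            raise ValueError("background noise SD must be >= 0")
        if self.offset_um[0] < 0 or self.offset_um[1] < 0:
            raise ValueError("offset mean and SD must be >= 0")
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative particle counts: {bad}")
        unknown = set(self.counts) - {"A_only", "B_only", "AB"}
        if unknown:
            raise ValueError(f"unknown particle classes: {unknown}")

    @property
    def n_particles(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        d = self.__dict__.copy()
        return json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o)


@dataclass(frozen=True)
class GroundTruthParticle:
    """One planted particle with its true per-channel state."""

    particle_id: int
    klass: str  # A_only | B_only | AB
    positions_um: dict[str, tuple[float, float]]  # channel -> (x_um, y_um)
    intensities: dict[str, float]  # channel -> true total intensity (a.u.)
    true_offset_um: float  # 0 for single-channel particles


def _add_spot(img: np.ndarray, x_px: float, y_px: float, sigma: float,
              total: float) -> None:
    """Add an isotropic Gaussian spot whose pixel-integrated mass is `total`.

    Pixels are treated as unit squares; the per-pixel contribution is the
    exact integral of the Gaussian density over the square (erf form), so
    with the spot well inside the grid the added mass equals `total` up to
    tail truncation beyond 6 sigma (< 1e-8 relative).
    """
    h, w = img.shape
    r = int(math.ceil(6.0 * sigma))
    x0, x1 = max(0, int(math.floor(x_px)) - r), min(w, int(math.floor(x_px)) + r + 2)
    y0, y1 = max(0, int(math.floor(y_px)) - r), min(h, int(math.floor(y_px)) + r + 2)
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    fx = 0.5 * (erf((xs + 0.5 - x_px) / (_SQRT2 * sigma))
                - erf((xs - 0.5 - x_px) / (_SQRT2 * sigma)))
    fy = 0.5 * (erf((ys + 0.5 - y_px) / (_SQRT2 * sigma))
                - erf((ys - 0.5 - y_px) / (_SQRT2 * sigma)))
    img[y0:y1, x0:x1] += total * np.outer(fy, fx)


def _place_positions(rng: np.random.Generator, n: int, lo: np.ndarray,
                     hi: np.ndarray, min_sep: float,
                     max_tries: int = 20000) -> np.ndarray:
    """Uniform positions in the box [lo, hi], optionally dart-thrown."""
    if n == 0:
        return np.empty((0, 2))
    if np.any(hi <= lo):
        raise ValueError(
            "field too small: margin leaves no room to place particles"
        )
    if min_sep <= 0:
        return rng.uniform(lo, hi, size=(n, 2))
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                f"field too small to place {n} particles with "
                f"min_separation_px={min_sep}"
            )
        p = rng.uniform(lo, hi)
        tries += 1
        if all(np.hypot(*(p - q)) >= min_sep for q in placed):
            placed.append(p)
    return np.asarray(placed)


def make_scene(spec: SceneSpec) -> tuple[list[GroundTruthParticle], ImageFrame]:
    """Render one two-channel scene and return (ground truth, frame).

    Deterministic given ``spec.seed``.  Raises ``ValueError`` if the field
    cannot accommodate the requested counts with the stated margin.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_px
    m = spec.margin_px
    lo = np.array([m, m], dtype=float)
    hi = np.array([w - 1 - m, h - 1 - m], dtype=float)

    order = [("A_only", spec.counts.get("A_only", 0)),
             ("B_only", spec.counts.get("B_only", 0)),
             ("AB", spec.counts.get("AB", 0))]
    n_total = sum(n for _, n in order)
    base = _place_positions(rng, n_total, lo, hi, spec.min_separation_px)

    px = spec.pixel_size_um
    off_mean, off_sd = spec.offset_um
    particles: list[GroundTruthParticle] = []
    i = 0
    for klass, n in order:
        for _ in range(n):
            pos = base[i]
            channels = {"A_only": ["A"], "B_only": ["B"], "AB": ["A", "B"]}[klass]
            positions: dict[str, tuple[float, float]] = {}
            intensities: dict[str, float] = {}
            offset = 0.0
            if klass == "AB":
                # offset length truncated at zero; direction uniform,
                # resampled until channel-B spot stays inside the margin box
                offset = -1.0
                while offset < 0:
                    offset = rng.normal(off_mean, off_sd) if off_sd > 0 else off_mean
                for _try in range(200):
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    bpos = pos + (offset / px) * np.array([math.cos(theta), math.sin(theta)])
                    if np.all(bpos >= lo) and np.all(bpos <= hi):
                        break
                else:  # pragma: no cover - margin >> offset in practice
                    bpos = pos
                    offset = 0.0
                positions["A"] = (pos[0] * px, pos[1] * px)
                positions["B"] = (bpos[0] * px, bpos[1] * px)
            else:
                positions[channels[0]] = (pos[0] * px, pos[1] * px)
            for c in channels:
                mu, sd = spec.intensity_law[c]
                intensities[c] = float(rng.lognormal(mu, sd)) if sd > 0 else math.exp(mu)
            particles.append(
                GroundTruthParticle(i, klass, positions, intensities, float(offset))
            )
            i += 1

    bg_mean, noise_sd = spec.background
    grids: dict[str, np.ndarray] = {}
    for c in ("A", "B"):
        img = np.full((h, w), bg_mean, dtype=float)
        for p in particles:
            if c in p.positions_um:
                x_um, y_um = p.positions_um[c]
                _add_spot(img, x_um / px, y_um / px, spec.psf_sigma_px,
                          p.intensities[c])
        grids[c] = img
    # noise drawn after all placement randomness, one channel at a time,
    # so placements are invariant to the noise level
    for c in ("A", "B"):
        if noise_sd > 0:
            grids[c] = grids[c] + rng.normal(0.0, noise_sd, size=(h, w))

    frame = ImageFrame(grids, px, frame_id=f"scene_{spec.seed}")
    return particles, frame


def ground_truth_frame(particles: list[GroundTruthParticle]) -> pd.DataFrame:
    """Tabulate ground truth, one row per particle (NaN for absent channels)."""
    rows = []
    for p in particles:
        row: dict = {"particle_id": p.particle_id, "klass": p.klass,
                     "true_offset_um": p.true_offset_um}
        for c in ("A", "B"):
            if c in p.positions_um:
                row[f"x_um_{c}"], row[f"y_um_{c}"] = p.positions_um[c]
                row[f"intensity_{c}"] = p.intensities[c]
            else:
                row[f"x_um_{c}"] = row[f"y_um_{c}"] = row[f"intensity_{c}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_scene(spec: SceneSpec, out_tiff, out_truth_csv) -> tuple[list[GroundTruthParticle], ImageFrame]:
    """Render and persist a scene (TIFF + ground-truth CSV with spec header)."""
    particles, frame = make_scene(spec)
    frame.to_tiff(out_tiff)
    write_ground_truth(particles, spec, out_truth_csv)
    return particles, frame


def write_ground_truth(particles: list[GroundTruthParticle], spec: SceneSpec,
                       path) -> None:
    df = ground_truth_frame(particles)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# spec: {spec.to_json()}\n")
        df.to_csv(fh, index=False)


def make_point_sets(n_A: int, n_B: int, field_um: tuple[float, float],
                    paired_fraction: float, offset_um: float,
                    seed: int = 0) -> tuple[PointSet, PointSet]:
    """Two planar point sets with a planted associated fraction.

    ``round(paired_fraction * min(n_A, n_B))`` B points are placed at
    distance ``offset_um`` (uniform angle) from distinct A points; all
    remaining points of both sets are CSR-uniform over the field.
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must be in [0, 1]")
    if n_A < 0 or n_B < 0:
        raise ValueError("point counts must be >= 0")
    w, hgt = field_um
    rng = np.random.default_rng(seed)
    a = rng.uniform([0.0, 0.0], [w, hgt], size=(n_A, 2))
    n_pairs = round(paired_fraction * min(n_A, n_B))
    b = np.empty((n_B, 2))
    for k in range(n_pairs):
        # anchor on the k-th A point; resample angle until inside the field
        for _try in range(1000):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            q = a[k] + offset_um * np.array([math.cos(theta), math.sin(theta)])
            if 0.0 <= q[0] <= w and 0.0 <= q[1] <= hgt:
                b[k] = q
                break
        else:
            raise ValueError(
                "cannot construct paired point inside the field; "
                "offset too large for the field size"
            )
    if n_B > n_pairs:
        b[n_pairs:] = rng.uniform([0.0, 0.0], [w, hgt], size=(n_B - n_pairs, 2))
    return (PointSet(a, field_um, label="A"), PointSet(b, field_um, label="B"))


@dataclass(frozen=True)
class PeptideSpec:
    """Design of a synthetic six-sample peptide intensity table.

    Background proteins have equal expected intensity in all samples;
    enriched proteins have FASS expectation ``fold_effect`` times the SYN
    expectation (depleted: the inverse).  Replicate noise is multiplicative
    lognormal with coefficient of variation ``replicate_cv`` and unit mean.
    """

    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (1, 6)  # uniform inclusive
    frac_enriched: float = 0.05
    frac_depleted: float = 0.0
    fold_effect: float = 3.0
    replicate_cv: float = 0.2
    n_syn: int = 3
    n_fass: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_enriched + self.frac_depleted > 1.0:
            raise ValueError("frac_enriched + frac_depleted must be <= 1")
        if not (0 <= self.frac_enriched <= 1 and 0 <= self.frac_depleted <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fold_effect <= 1.0:
            raise ValueError("fold_effect must exceed 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.peptides_per_protein[0] < 1:
            raise ValueError("proteins need at least one peptide")


def make_peptide_table(spec: PeptideSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format peptide table plus per-protein ground-truth class.

    Returns
    -------
    table
        Columns ``protein_id, peptide_id, unique_flag, sample, intensity``;
        samples are ``SYN_1..n_syn`` and ``FASS_1..n_fass``.
    truth
        Series indexed by protein_id with values in
        {``background``, ``enriched``, ``depleted``}.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    n_enr = round(spec.frac_enriched * n)
    n_dep = round(spec.frac_depleted * n)
    classes = np.array(
        ["enriched"] * n_enr + ["depleted"] * n_dep
        + ["background"] * (n - n_enr - n_dep)
    )
    rng.shuffle(classes)
    protein_ids = [f"P{i:05d}" for i in range(n)]
    truth = pd.Series(classes, index=pd.Index(protein_ids, name="protein_id"),
                      name="true_class")

    lo, hi = spec.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=n)
    samples = ([f"SYN_{i + 1}" for i in range(spec.n_syn)]
               + [f"FASS_{i + 1}" for i in range(spec.n_fass)])
    is_fass = np.array([s.startswith("FASS") for s in samples])
    sigma = math.sqrt(math.log1p(spec.replicate_cv ** 2))

    rows: list[dict] = []
    for pid, klass, npep in zip(protein_ids, classes, n_peps):
        base = 10.0 ** rng.normal(6.0, 0.5)  # protein abundance, a.u.
        fold = {"enriched": spec.fold_effect,
                "depleted": 1.0 / spec.fold_effect,
                "background": 1.0}[klass]
        for j in range(npep):
            pep_factor = 10.0 ** rng.normal(0.0, 0.4)  # ionization efficiency
            expected = base * pep_factor
            if sigma > 0:
                noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=len(samples)))
            else:
                noise = np.ones(len(samples))
            vals = expected * np.where(is_fass, fold, 1.0) * noise
            for s, v in zip(samples, vals):
                rows.append({"protein_id": pid, "peptide_id": f"{pid}_pep{j + 1}",
                             "unique_flag": True, "sample": s,
                             "intensity": float(v)})
    return pd.DataFrame(rows), truth
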