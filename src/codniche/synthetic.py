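"""Synthetic landmark and isotope data with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every downstream stage is testable by parameter recovery, without any
external download:

* two morphotype shape classes built from a stylized 21-landmark lateral
  cod template, the second class differing mainly in its head landmarks
  (contracted toward the head centroid by ``head_offset_magnitude``);
* allometric scaling of whole configurations with fork length
  (``allometric_exponent`` = 1 is isometry), random rotation/translation,
  per-photo pixel scales, and Gaussian digitization noise;
* paired-tissue isotope values with a latent per-fish mean (between-fish
  variance sigma2_B, optionally trending with fork length), tissue offsets
  equal to the diet-tissue discrimination factors (so raw values are
  emitted *before* correction and the pipeline's correction step is
  exercised), within-fish noise sigma2_W, and a deterministic count of
  fish missing one tissue.

Default parameters mirror the magnitudes of the study population this
package analyses: fork lengths Normal(388.6, 57.6^2) mm, group means from
the printed tissue summaries, sigma2_B = 0.36 / sigma2_W = 0.24 per-mil
squared (an expected IS of 0.40), and a 31% unpaired-tissue fraction.

A single master seed drives everything; sub-streams are derived per stage,
so identical truth parameters give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import DiscriminationFactors
from .landmarks import LandmarkConfiguration, write_tps

#: stylized lateral cod outline: x toward the tail, y up, body length 1
BASE_TEMPLATE = np.array(
    [
        [0.00, 0.000],   # 0  snout tip
        [0.08, 0.035],   # 1  anterior eye
        [0.13, 0.035],   # 2  posterior eye
        [0.18, 0.080],   # 3  top of cranium
        [0.12, -0.040],  # 4  posterior maxilla
        [0.25, 0.060],   # 5  posterior operculum (dorsal)
        [0.24, -0.070],  # 6  posterior operculum (ventral)
        [0.18, -0.090],  # 7  isthmus / ventral head
        [0.33, 0.120],   # 8  first dorsal fin origin
        [0.45, 0.120],   # 9  first dorsal fin end
        [0.52, 0.110],   # 10 second dorsal fin origin
        [0.78, 0.070],   # 11 third dorsal fin end
        [0.88, 0.035],   # 12 caudal peduncle (dorsal)
        [1.00, 0.000],   # 13 posterior caudal peduncle (fork length)
        [0.88, -0.035],  # 14 caudal peduncle (ventral)
        [0.78, -0.060],  # 15 second anal fin end
        [0.55, -0.090],  # 16 anal fin origin
        [0.50, -0.095],  # 17 vent
        [0.28, -0.100],  # 18 pelvic fin origin
        [0.30, -0.020],  # 19 pectoral fin origin
        [0.40, -0.110],  # 20 ventral body midpoint
    ]
)

#: indices displaced between the two morphotype templates
HEAD_LANDMARKS = (0, 1, 2, 3, 4, 5, 6, 7)

N_TEMPLATE_LANDMARKS = len(BASE_TEMPLATE)

# sub-stream indices off the master seed
_STREAM_FISH, _STREAM_LANDMARKS, _STREAM_ISOTOPES, _STREAM_QUALITY = range(4)


def make_templates(head_offset_magnitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Morphotype templates: (large-head reference, contracted-head variant).

    Template 2's head landmarks move toward the head centroid by the given
    dimensionless fraction, yielding the smaller-head, slender-headed class.
    """
    t1 = BASE_TEMPLATE.copy()
    t2 = BASE_TEMPLATE.copy()
    head = t2[list(HEAD_LANDMARKS)]
    centroid = head.mean(axis=0)
    t2[list(HEAD_LANDMARKS)] = centroid + (1.0 - head_offset_magnitude) * (head - centroid)
    return t1, t2


def _default_group_means() -> dict[str, tuple[float, float]]:
    # diet-referenced group means (‰) per morphotype, after the printed
    # tissue summaries of the study population
    return {"d13C": (-21.05, -20.70), "d15N": (15.03, 15.40)}


@dataclass
class SyntheticTruth:
    """Generator parameters = the ground truth recovery targets."""

    n_fish: int = 100
    morphotype_fractions: tuple[float, ...] = (26 / 45, 19 / 45)
    head_offset_magnitude: float = 0.25
    digitization_sd: float = 2.0          # mm
    fork_length_mean: float = 388.6       # mm
    fork_length_sd: float = 57.6          # mm
    allometric_exponent: float = 1.0      # 1 = isometry
    isotope_group_means: dict[str, tuple[float, float]] = field(
        default_factory=_default_group_means
    )
    sigma2_between: float = 0.36          # ‰², per-fish intercept variance
    sigma2_within: float = 0.24           # ‰², residual (tissue/time) variance
    tissue_offsets: DiscriminationFactors = field(default_factory=DiscriminationFactors)
    fork_length_slope: float = 0.0        # ‰ per mm on the latent mean
    year_labels: tuple[int, ...] = (2018, 2019)
    year_fractions: tuple[float, ...] = (19 / 45, 26 / 45)
    missing_tissue_fraction: float = 0.31
    shape_templates: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ValueError("n_fish must be >= 2")
        for name in ("sigma2_between", "sigma2_within", "digitization_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_tissue_fraction < 1:
            raise ValueError("missing_tissue_fraction must be in [0, 1)")
        if not np.isclose(sum(self.morphotype_fractions), 1.0):
            raise ValueError("morphotype_fractions must sum to 1")
        if not np.isclose(sum(self.year_fractions), 1.0):
            raise ValueError("year_fractions must sum to 1")
        if self.shape_templates is not None:
            for t in self.shape_templates:
                if np.asarray(t).shape != (N_TEMPLATE_LANDMARKS, 2):
                    raise ValueError(
                        f"templates must have {N_TEMPLATE_LANDMARKS} landmarks"
                    )

    def templates(self) -> tuple[np.ndarray, np.ndarray]:
        if self.shape_templates is not None:
            return self.shape_templates
        return make_templates(self.head_offset_magnitude)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stream])


def truth_is(truth: SyntheticTruth) -> float:
    """The IS value implied by the generator: sigma2_W / (sigma2_W + sigma2_B)."""
    total = truth.sigma2_within + truth.sigma2_between
    if total == 0:
        raise ZeroDivisionError("both variance components are zero: IS undefined")
    return truth.sigma2_within / total


def _deterministic_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    counts = [int(round(n * f)) for f in fractions]
    counts[-1] = n - sum(counts[:-1])
    return counts


def fish_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Shared per-fish frame: id, morphotype, fork length (mm), year.

    Both :func:`simulate_landmarks` and :func:`simulate_isotopes` derive
    from this table, so a single seed yields one coherent population.
    """
    rng = truth._rng(_STREAM_FISH)
    n = truth.n_fish
    types = np.repeat(
        np.arange(1, len(truth.morphotype_fractions) + 1),
        _deterministic_counts(n, truth.morphotype_fractions),
    )
    rng.shuffle(types)
    fl = rng.normal(truth.fork_length_mean, truth.fork_length_sd, size=n)
    fl = np.clip(fl, 50.0, None)  # guard against non-physical lengths
    years = np.repeat(
        list(truth.year_labels), _deterministic_counts(n, truth.year_fractions)
    )
    rng.shuffle(years)
    width = len(str(n))
    return pd.DataFrame(
        {
            "fish_id": [f"fish{str(i + 1).zfill(width)}" for i in range(n)],
            "morphotype": types,
            "fork_length_mm": fl,
            "year": years,
        }
    )


def simulate_landmarks(
    truth: SyntheticTruth,
) -> tuple[list[LandmarkConfiguration], np.ndarray]:
    """Landmark configurations (image units + per-photo scale) and true labels.

    Each specimen is its morphotype template, isotropically scaled by fork
    length through the allometric exponent, randomly rotated and
    translated, with Gaussian digitization noise of sd ``digitization_sd``
    (mm) added per coordinate, then divided by a per-photo mm/px scale.
    """
    templates = truth.templates()
    fish = fish_table(truth)
    rng = truth._rng(_STREAM_LANDMARKS)
    configs: list[LandmarkConfiguration] = []
    for row in fish.itertuples():
        template = templates[row.morphotype - 1]
        size_mm = truth.fork_length_mean * (
            row.fork_length_mm / truth.fork_length_mean
        ) ** truth.allometric_exponent
        theta = rng.uniform(-np.pi, np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = rng.uniform(100.0, 600.0, size=2)
        coords_mm = template * size_mm @ rot.T + shift
        if truth.digitization_sd > 0:
            coords_mm = coords_mm + rng.normal(
                0.0, truth.digitization_sd, size=coords_mm.shape
            )
        px_scale = rng.uniform(0.3, 0.5)  # mm per pixel
        configs.append(
            LandmarkConfiguration(
                specimen_id=row.fish_id,
                coords=coords_mm / px_scale,
                scale=px_scale,
                image=f"{row.fish_id}.jpg",
                landmark_quality=(3,) * N_TEMPLATE_LANDMARKS,
                photo_quality=3,
                year=int(row.year),
            )
        )
    return configs, fish["morphotype"].to_numpy()


def simulate_isotopes(truth: SyntheticTruth) -> pd.DataFrame:
    """Long-format raw (pre-correction) isotope table, RBC + plasma per fish.

    Per fish i and isotope, the latent mean is
    mu_i ~ Normal(group mean + slope * (FL_i - mean FL), sigma2_B);
    the observation for tissue t is mu_i + Delta(isotope, t) + eps with
    eps ~ Normal(0, sigma2_W).  A deterministic count
    round(n * missing_tissue_fraction) of fish lose one tissue at random.
    """
    fish = fish_table(truth)
    rng = truth._rng(_STREAM_ISOTOPES)
    n = truth.n_fish
    rows = []
    latent: dict[str, np.ndarray] = {}
    for iso, means in truth.isotope_group_means.items():
        mu = np.array([means[t - 1] for t in fish["morphotype"]], dtype=float)
        mu = mu + truth.fork_length_slope * (
            fish["fork_length_mm"].to_numpy() - truth.fork_length_mean
        )
        latent[iso] = mu + rng.normal(0.0, np.sqrt(truth.sigma2_between), size=n)
    for tissue in ("RBC", "plasma"):
        block = fish[["fish_id", "morphotype", "fork_length_mm", "year"]].copy()
        block["tissue"] = tissue
        for iso in truth.isotope_group_means:
            block[iso] = (
                latent[iso]
                + truth.tissue_offsets.delta(iso, tissue)
                + rng.normal(0.0, np.sqrt(truth.sigma2_within), size=n)
            )
        rows.append(block)
    records = pd.concat(rows, ignore_index=True)

    n_drop = int(round(n * truth.missing_tissue_fraction))
    if n_drop:
        dropped_fish = rng.choice(fish["fish_id"].to_numpy(), size=n_drop, replace=False)
        lost_tissue = rng.choice(["RBC", "plasma"], size=n_drop)
        kill = pd.MultiIndex.from_arrays([dropped_fish, lost_tissue])
        idx = pd.MultiIndex.from_frame(records[["fish_id", "tissue"]])
        records = records[~idx.isin(kill)].reset_index(drop=True)
    cols = ["fish_id", "tissue", "d13C", "d15N", "year", "fork_length_mm", "morphotype"]
    return records[cols]


def write_dataset(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit the generated study as files: TPS landmarks + the two CSV schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    configs, labels = simulate_landmarks(truth)
    fish = fish_table(truth)
    iso = simulate_isotopes(truth)
    paths = {
        "tps": outdir / "landmarks.tps",
        "specimens": outdir / "specimens.csv",
        "isotopes": outdir / "isotopes.csv",
        "truth_labels": outdir / "true_morphotypes.csv",
    }
    write_tps(configs, paths["tps"])
    fish[["fish_id", "fork_length_mm", "year"]].rename(
        columns={"fish_id": "specimen_id"}
    ).to_csv(paths["specimens"], index=False)
    iso[["fish_id", "tissue", "d13C", "d15N", "year"]].to_csv(
        paths["isotopes"], index=False
    )
    fish[["fish_id", "morphotype"]].to_csv(paths["truth_labels"], index=False)
    return paths


def with_seed(truth: SyntheticTruth, seed: int) -> SyntheticTruth:
    """Same truth, different master seed (convenience for replicate studies)."""
    return replace(truth, seed=seed)
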