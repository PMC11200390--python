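"""Synthetic radiomic feature tables with an ordinal latent class gradient.

The generator emulates the statistical structure the pipeline assumes about
slice-wise BPE radiomics: a low-dimensional latent space in which the four
ordinal classes (minimal/mild/moderate/marked) sit at equidistant positions
along one axis, patients contributing several mutually correlated slices,
class imbalance, and a high-dimensional feature vector obtained as a linear
map of the latent position plus feature noise.  Only features whose terminal
feature type is in ``signal_feature_types`` load on the class axis, so
importance reports have a known planted ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tables import FeatureName, FeatureTable, compose_feature_name, parse_feature_name

# Feature-type vocabularies per feature class, mirroring the standard
# radiomics-extractor output (first-order, 2-D shape, five texture families).
_FEATURE_TYPES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "shape2D": (
        "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
        "Sphericity", "MaximumDiameter", "MajorAxisLength", "MinorAxisLength",
        "Elongation",
    ),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
        "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
        "JointEntropy", "MCC", "MaximumProbability", "SumAverage",
        "SumEntropy", "SumSquares",
    ),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
}

_FILTER_TAGS = (
    "original",
    "log-sigma-1-0-mm-3D",
    "log-sigma-2-0-mm-3D",
    "log-sigma-3-0-mm-3D",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
    "lbp-2D",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
)

#: Feature types that carry the planted class signal by default: the
#: entropy/uniformity family that distinguishes homogeneous from
#: heterogeneous enhancement patterns.
DEFAULT_SIGNAL_TYPES = frozenset(
    {
        "Entropy",
        "Uniformity",
        "RunEntropy",
        "ZoneEntropy",
        "DependenceEntropy",
        "GrayLevelNonUniformityNormalized",
    }
)


def _base_blocks() -> list[list[str]]:
    """One block per (class, type): that type's names across filter tags.

    Shape descriptors are intensity-filter independent; they are emitted
    under two tags only (original and the LBP map, which shares the mask
    geometry) so that every type still has at least two name variants.
    """
    blocks: list[list[str]] = []
    for fclass, types in _FEATURE_TYPES.items():
        filters = ("original", "lbp-2D") if fclass == "shape2D" else _FILTER_TAGS
        for ftype in types:
            blocks.append([compose_feature_name(f, fclass, ftype) for f in filters])
    return blocks


def generate_feature_names(n_features: int) -> list[FeatureName]:
    """Deterministic list of ``n_features`` unique radiomic feature names.

    Names cross filter tags x feature classes x feature types, emitted in
    (class, type) blocks covering all filters of a type before the next
    type starts.  For n_features >= 100 every emitted feature type appears
    under at least two distinct filter/class combinations, so type-level
    aggregation is always exercised.  If more names are requested than the
    base cross product provides, extra generations reuse the filter tags
    with a ``-rK`` suffix.
    """
    if n_features < 10:
        raise ValueError("n_features must be >= 10")

    blocks = list(_base_blocks())
    generation = 1
    base = list(blocks)
    while sum(len(b) for b in blocks) < n_features:
        generation += 1
        blocks.extend(
            [_resuffix(raw, generation) for raw in block] for block in base
        )

    names: list[str] = []
    for block in blocks:
        remaining = n_features - len(names)
        if remaining == 0:
            break
        if remaining == 1 and n_features >= 100 and len(block) >= 2:
            # A singleton tail would leave its feature type un-aggregatable;
            # borrow one slot from the most recent block that can spare it.
            for donor in reversed(range(len(names))):
                donor_type = parse_feature_name(names[donor]).feature_type
                n_donor = sum(
                    1 for raw in names
                    if parse_feature_name(raw).feature_type == donor_type
                )
                if n_donor >= 3:
                    del names[donor]
                    break
            names.extend(block[:2])
        else:
            names.extend(block[:remaining])
    assert len(names) == n_features and len(set(names)) == n_features
    return [parse_feature_name(raw) for raw in names]


def _resuffix(raw: str, generation: int) -> str:
    name = parse_feature_name(raw)
    return compose_feature_name(
        f"{name.filter_tag}-r{generation}", name.feature_class, name.feature_type
    )


@dataclasses.dataclass
class SimulationSpec:
    """Conditions of a simulated study.

    ``effect_size`` is the separation between adjacent class means on latent
    axis 1, in units of the latent noise SD (which is 1); classes sit at
    0, e, 2e, 3e.  ``within_patient_sd`` is the SD of the patient-level
    latent offset shared by all slices of a patient, the source of
    within-patient correlation.  Only features whose terminal type is in
    ``signal_feature_types`` load on latent axis 1.
    """

    n_patients: int
    slices_per_patient: int | tuple[int, int] = 20
    n_features: int = 1192
    d_latent: int = 4
    class_probs: tuple[float, float, float, float] = (0.4, 0.25, 0.2, 0.15)
    effect_size: float = 3.0
    within_patient_sd: float = 0.2
    noise_sd: float = 0.5
    #: None selects the default entropy/uniformity family restricted to the
    #: types actually present at this n_features; an explicit set is strict.
    signal_feature_types: frozenset[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.n_features < 10:
            raise ValueError("n_features must be >= 10")
        if self.d_latent < 1:
            raise ValueError("d_latent must be positive")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or (probs <= 0).any():
            raise ValueError("class_probs must be 4 positive reals")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must sum to 1 within 1e-12")
        if self.effect_size < 0 or self.within_patient_sd < 0:
            raise ValueError("effect_size and within_patient_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if isinstance(self.slices_per_patient, tuple):
            lo, hi = self.slices_per_patient
            if lo < 1 or hi < lo:
                raise ValueError("invalid slices_per_patient range")
        elif self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be positive")


def simulate(spec: SimulationSpec) -> FeatureTable:
    """Draw a feature table under ``spec``; deterministic given ``spec.seed``.

    Per patient: one class from ``class_probs`` and a latent offset
    ~ N(0, within_patient_sd * I_d).  Per slice: latent position z =
    class mean (on axis 1) + patient offset + N(0, I_d); features =
    loading matrix @ z + N(0, noise_sd).  All slices inherit the patient's
    class label.
    """
    rng = np.random.default_rng(spec.seed)
    names = generate_feature_names(spec.n_features)

    # Loading matrix: axis 1 loads only on signal feature types, with a
    # planted positive direction; remaining axes load on every feature with
    # N(0, 1/sqrt(d)) entries so column variances stay comparable.
    d = spec.d_latent
    scale = 1.0 / np.sqrt(d)
    loadings = rng.normal(0.0, scale, size=(spec.n_features, d))
    present = {n.feature_type for n in names}
    signal_types = spec.signal_feature_types
    if signal_types is None:
        signal_types = frozenset(DEFAULT_SIGNAL_TYPES & present)
        if not signal_types:
            raise ValueError(
                "no default signal feature types present; pass "
                "signal_feature_types explicitly"
            )
    else:
        unknown = set(signal_types) - present
        if unknown:
            raise ValueError(
                f"signal_feature_types not present in generated names: {sorted(unknown)}"
            )
    is_signal = np.array(
        [n.feature_type in signal_types for n in names], dtype=bool
    )
    signal_load = np.abs(rng.normal(1.0, 0.2, size=int(is_signal.sum()))) * scale
    loadings[:, 0] = 0.0
    loadings[is_signal, 0] = signal_load

    classes = rng.choice(4, size=spec.n_patients, p=np.asarray(spec.class_probs)) + 1
    offsets = rng.normal(0.0, spec.within_patient_sd, size=(spec.n_patients, d))
    if isinstance(spec.slices_per_patient, tuple):
        lo, hi = spec.slices_per_patient
        counts = rng.integers(lo, hi + 1, size=spec.n_patients)
    else:
        counts = np.full(spec.n_patients, spec.slices_per_patient)

    patient_idx = np.repeat(np.arange(spec.n_patients), counts)
    n_slices = len(patient_idx)
    class_means = np.zeros((4, d))
    class_means[:, 0] = spec.effect_size * np.arange(4)

    z = (
        class_means[classes[patient_idx] - 1]
        + offsets[patient_idx]
        + rng.normal(0.0, 1.0, size=(n_slices, d))
    )
    values = z @ loadings.T + rng.normal(0.0, spec.noise_sd, size=(n_slices, spec.n_features))

    width = len(str(spec.n_patients))
    patient_ids = np.array(
        [f"P{i + 1:0{width}d}" for i in patient_idx], dtype=object
    )
    within = np.concatenate([np.arange(c) for c in counts])
    slice_ids = np.array(
        [f"{p}_S{s + 1:03d}" for p, s in zip(patient_ids, within)], dtype=object
    )

    return FeatureTable(
        patient_ids,
        slice_ids,
        classes[patient_idx],
        [n.raw for n in names],
        values,
    )


#: Named fixture registry used throughout the test suite.  All are small
#: (<= 2000 slices) and fully determined by (name, seed).
FIXTURES: dict[str, dict] = {
    # 8 patients x 5 slices, 40 features: fast enough for exact-Shapley
    # equivalence checks on every slice.  The first 40 names are first-order
    # types, so the signal set is restricted to Entropy.
    "tiny": dict(n_patients=8, slices_per_patient=5, n_features=40,
                 effect_size=3.0, noise_sd=0.5,
                 signal_feature_types=frozenset({"Entropy"})),
    # Strong ordinal signal: a linear read-out of the first PCs separates
    # the classes, so end-to-end accuracy >= 0.85 is attainable.  300
    # features cover all first-order and shape types plus early GLCM types;
    # the planted signal sits on Entropy and Uniformity.  Class probabilities
    # are imbalanced but keep the rarest class frequent enough that the 10%
    # split minimum is satisfiable with patient-sized atoms.
    "separable": dict(n_patients=100, slices_per_patient=20, n_features=300,
                      effect_size=3.0, noise_sd=0.5,
                      class_probs=(0.35, 0.25, 0.2, 0.2),
                      signal_feature_types=frozenset({"Entropy", "Uniformity"})),
    # No class signal at all: any apparent skill is overfitting.
    "null": dict(n_patients=80, slices_per_patient=12, n_features=200,
                 effect_size=0.0, noise_sd=0.5,
                 class_probs=(0.35, 0.25, 0.2, 0.2),
                 signal_feature_types=frozenset({"Entropy"})),
    # Stronger class imbalance than the default.
    "imbalanced": dict(n_patients=60, slices_per_patient=20, n_features=200,
                       effect_size=3.0, noise_sd=0.5,
                       class_probs=(0.55, 0.2, 0.15, 0.1),
                       signal_feature_types=frozenset({"Entropy"})),
}


def make_fixture(name: str, seed: int = 0) -> FeatureTable:
    """Generate a registered named fixture (deterministic given seed)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return simulate(SimulationSpec(seed=seed, **FIXTURES[name]))
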