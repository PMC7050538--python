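"""Synthetic activity datasets with the structure the benchmark assumes.

The generator emulates what the real competition data look like
statistically, so every pipeline stage can run and be tested offline:

* sparse non-negative integer descriptor matrices whose column
  frequencies are heavy-tailed (a few ubiquitous substructures, a long
  tail of rare ones) — a power-law column weight thinned by per-column
  Bernoulli inclusion, positive counts drawn 1 + negative-binomial;
* train/test vocabulary mismatch: the test split observes only a
  ``vocab_overlap`` fraction of the training columns plus novel ones,
  exercising vocabulary alignment;
* a time-split-like covariate shift: test column frequencies are
  perturbed by a log-normal factor of strength ``shift_strength``;
* activities produced by mechanisms of controllable complexity — a
  plain weighted sum (log D-like partitioning), a saturating
  single-index response optionally pushed through the Cheng-Prusoff
  relation with per-molecule [S]/Km jitter (pIC50-like), and a
  product/ratio composition of several latent sub-responses with
  heteroscedastic noise (bioavailability-like, intentionally hard);
* optional floor-censoring: assay panels report all activities beyond
  the measured concentration range as one constant, so everything below
  ``censor_floor`` is clamped to it.

Everything is a pure function of the spec's seed: the same spec
regenerates the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import ActivityTable, AlignedDataset, align_vocabularies
from .molgraph import Atom, Bond, MolecularGraph

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "generate_aligned",
    "mechanism_activity",
    "toy_molecules",
    "EXPECTED_AP_FINGERPRINTS",
]

MECHANISMS = ("linear_logD_like", "single_index_nonlinear", "composed_multimechanism")

# positive counts are 1 + NegBin(r, p) with this extra mean
_EXTRA_COUNT_MEAN = 2.0
_BETA_SPARSITY = 0.2  # fraction of descriptors that truly carry signal


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic target dataset.

    Defaults are the generator's reference conditions: a desk-scale
    split (3000 train / 600 test molecules, 300 training descriptors —
    the molecule-to-descriptor ratio of the mid-size real targets) with
    90 % zeros, 80 % train/test vocabulary overlap, a mild frequency
    shift between splits and moderate activity noise.
    """

    n_train: int = 3000
    n_test: int = 600
    n_descriptors: int = 300
    zero_fraction: float = 0.9
    count_dispersion: float = 1.0
    mechanism: str = "linear_logD_like"
    noise_sd: float = 0.3
    censor_floor: float | None = None
    vocab_overlap: float = 0.8
    shift_strength: float = 0.2
    jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test, self.n_descriptors) < 1:
            raise ValueError("sizes must be >= 1")
        if not (0.0 < self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must be in (0,1)")
        if not (0.0 < self.vocab_overlap <= 1.0):
            raise ValueError("vocab_overlap must be in (0,1]")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.noise_sd < 0 or self.shift_strength < 0:
            raise ValueError("noise_sd and shift_strength must be >= 0")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )


@dataclass
class GroundTruth:
    """What the generator really did: mechanism parameters and clean signal."""

    mechanism: str
    params: dict
    noiseless_train: np.ndarray
    noiseless_test: np.ndarray
    train_columns: list[str]
    test_columns: list[str]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))


def _solve_inclusion_scale(weights: np.ndarray, target_mean: float) -> float:
    """Scale s with mean(clip(s*w, 0, 1)) == target_mean, by bisection."""
    lo, hi = 0.0, 1.0
    while np.clip(hi * weights, 0, 1).mean() < target_mean:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.clip(mid * weights, 0, 1).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_counts(
    rng: np.random.Generator, n_rows: int, inclusion: np.ndarray, dispersion: float
) -> np.ndarray:
    """Zero-inflated overdispersed counts: Bernoulli(pi_c) * (1 + NegBin)."""
    present = rng.random((n_rows, inclusion.size)) < inclusion[None, :]
    r = dispersion
    p = r / (r + _EXTRA_COUNT_MEAN)
    extra = rng.negative_binomial(r, p, size=present.shape)
    return present * (1 + extra)


def _index_stats(pi: np.ndarray, beta: np.ndarray, dispersion: float) -> tuple[float, float]:
    """Analytic mean/sd of X @ beta under the count model with inclusion pi."""
    m = 1.0 + _EXTRA_COUNT_MEAN
    var_extra = _EXTRA_COUNT_MEAN + _EXTRA_COUNT_MEAN**2 / dispersion
    mean_c = pi * m
    var_c = pi * var_extra + pi * (1.0 - pi) * m * m
    mean = float(mean_c @ beta)
    sd = float(np.sqrt(var_c @ np.square(beta)))
    return mean, max(sd, 1e-12)


def _standardized_index(x: np.ndarray, beta, center, scale) -> np.ndarray:
    return (x @ np.asarray(beta) - center) / scale


def _activities(
    x: np.ndarray, mechanism: str, params: dict, s_over_km=0.0
) -> np.ndarray:
    """Vectorised noiseless mechanism response for a count matrix."""
    x = np.asarray(x, dtype=float)
    if mechanism == "linear_logD_like":
        z = _standardized_index(x, params["beta"], params["center"], params["scale"])
        return params["intercept"] + params["slope"] * z
    if mechanism == "single_index_nonlinear":
        z = _standardized_index(x, params["beta"], params["center"], params["scale"])
        pki = params["pki_low"] + params["pki_span"] * _sigmoid(z)
        s_over_km = np.asarray(s_over_km, dtype=float)
        # pIC50 = -log10 IC50 with IC50 = Ki (1 + [S]/Km) and Ki = 10^-pKi
        ki = np.power(10.0, -pki)
        ic50 = ki * (1.0 + s_over_km)
        return -np.log10(ic50)
    if mechanism == "composed_multimechanism":
        subs = []
        for k in (1, 2, 3):
            subs.append(
                _sigmoid(
                    _standardized_index(
                        x, params[f"beta{k}"], params[f"center{k}"], params[f"scale{k}"]
                    )
                )
            )
        r1, r2, r3 = subs
        # uptake * survival-of-extraction over a clearance-like denominator
        return np.log10((r1 * (1.0 - 0.8 * r2)) / (r3 + 0.1) + 0.01) + 1.0
    raise ValueError(f"unknown mechanism {mechanism!r}")


def mechanism_activity(counts, mechanism: str, params: dict, s_over_km: float = 0.0) -> float:
    """Noiseless activity of one descriptor row under a mechanism.

    ``counts`` is a 1-D count vector aligned with ``params['columns']``.
    For the single-index mechanism, ``s_over_km`` is the per-molecule
    substrate-to-Michaelis ratio fed through the Cheng-Prusoff relation;
    0 collapses the response to the pKi-like value.
    """
    row = np.asarray(counts, dtype=float).reshape(1, -1)
    if row.shape[1] != len(params["columns"]):
        raise ValueError(
            f"row has {row.shape[1]} counts but params describe "
            f"{len(params['columns'])} descriptors"
        )
    return float(_activities(row, mechanism, params, s_over_km=s_over_km)[0])


def _make_params(
    rng: np.random.Generator,
    columns: list[str],
    pi_full: np.ndarray,
    spec: SyntheticSpec,
    n_signal_columns: int | None = None,
) -> dict:
    """Mechanism parameters; index scalings are analytic, not data-fitted.

    Signal coefficients live only on the first ``n_signal_columns``
    entries (the training-chemistry vocabulary): novel test-only
    substructures contribute no activity, so a model trained on the
    training split can in principle recover the whole clean signal.
    """
    p_tot = len(columns)
    if n_signal_columns is None:
        n_signal_columns = p_tot

    def sparse_beta() -> np.ndarray:
        beta = rng.normal(0.0, 1.0, size=p_tot)
        mask = rng.random(p_tot) < _BETA_SPARSITY
        mask[n_signal_columns:] = False
        if not mask.any():
            mask[rng.integers(n_signal_columns)] = True
        return beta * mask

    params: dict = {"columns": list(columns)}
    if spec.mechanism == "composed_multimechanism":
        for k in (1, 2, 3):
            beta = sparse_beta()
            center, scale = _index_stats(pi_full, beta, spec.count_dispersion)
            params[f"beta{k}"] = beta
            params[f"center{k}"] = center
            params[f"scale{k}"] = scale
        return params
    beta = sparse_beta()
    center, scale = _index_stats(pi_full, beta, spec.count_dispersion)
    params.update(beta=beta, center=center, scale=scale)
    if spec.mechanism == "linear_logD_like":
        params.update(intercept=2.5, slope=1.0)  # log D-like 0..5 range
    else:
        params.update(pki_low=4.5, pki_span=3.0)  # pKi-like 4.5..7.5
    return params


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ActivityTable, ActivityTable, GroundTruth]:
    """Generate (train, test, ground truth) for one synthetic target.

    The two tables are alignment-ready: the test split shares
    ``round(vocab_overlap * n_descriptors)`` of the training columns and
    carries novel columns for the rest, like a time-later assay batch.
    """
    ss = np.random.SeedSequence(spec.seed)
    structure_rng, train_rng, test_rng, noise_rng = map(
        np.random.default_rng, ss.spawn(4)
    )

    p = spec.n_descriptors
    n_shared = max(1, round(spec.vocab_overlap * p))
    n_novel = p - n_shared
    p_tot = p + n_novel
    names = [f"D{i:05d}" for i in range(p_tot)]

    # heavy-tailed column weights, shuffled so rank is not column order
    weights = np.arange(1, p_tot + 1, dtype=float) ** -1.0
    weights = weights[structure_rng.permutation(p_tot)]
    scale = _solve_inclusion_scale(weights[:p], 1.0 - spec.zero_fraction)
    pi_full = np.clip(scale * weights, 0.0, 1.0)

    train_cols = list(range(p))
    shared = np.sort(structure_rng.choice(p, size=n_shared, replace=False))
    test_cols = [*shared.tolist(), *range(p, p_tot)]

    pi_train = pi_full[train_cols]
    shift = np.exp(
        spec.shift_strength * structure_rng.normal(size=len(test_cols))
    )
    pi_test = np.clip(pi_full[test_cols] * shift, 0.0, 1.0)

    x_train = _draw_counts(train_rng, spec.n_train, pi_train, spec.count_dispersion)
    x_test = _draw_counts(test_rng, spec.n_test, pi_test, spec.count_dispersion)

    params = _make_params(structure_rng, names, pi_full, spec, n_signal_columns=p)

    def full_matrix(x: np.ndarray, cols: list[int]) -> np.ndarray:
        full = np.zeros((x.shape[0], p_tot))
        full[:, cols] = x
        return full

    jitter_train = jitter_test = 0.0
    if spec.mechanism == "single_index_nonlinear":
        # [S]/Km = 10^(jitter_sd * N(0,1)): log-normal assay conditions, median 1
        jitter_train = np.power(
            10.0, spec.jitter_sd * noise_rng.normal(size=spec.n_train)
        )
        jitter_test = np.power(
            10.0, spec.jitter_sd * noise_rng.normal(size=spec.n_test)
        )
        params["s_over_km_train"] = jitter_train
        params["s_over_km_test"] = jitter_test

    clean_train = _activities(
        full_matrix(x_train, train_cols), spec.mechanism, params, jitter_train
    )
    clean_test = _activities(
        full_matrix(x_test, test_cols), spec.mechanism, params, jitter_test
    )

    def noisy(clean: np.ndarray, x_full: np.ndarray) -> np.ndarray:
        if spec.noise_sd == 0:
            return clean.copy()
        if spec.mechanism == "composed_multimechanism":
            r3 = _sigmoid(
                _standardized_index(
                    x_full, params["beta3"], params["center3"], params["scale3"]
                )
            )
            sd = spec.noise_sd * (0.5 + r3)  # heteroscedastic, clearance-linked
        else:
            sd = spec.noise_sd
        return clean + sd * noise_rng.normal(size=clean.shape)

    y_train = noisy(clean_train, full_matrix(x_train, train_cols))
    y_test = noisy(clean_test, full_matrix(x_test, test_cols))
    if spec.censor_floor is not None:
        y_train = np.maximum(y_train, spec.censor_floor)
        y_test = np.maximum(y_test, spec.censor_floor)

    train_names = [names[c] for c in train_cols]
    test_names = [names[c] for c in test_cols]
    train = ActivityTable(
        molecule_ids=[f"TRAIN_{i:05d}" for i in range(spec.n_train)],
        activities=y_train,
        descriptors=pd.DataFrame(x_train.astype(np.int64), columns=train_names),
    )
    test = ActivityTable(
        molecule_ids=[f"TEST_{i:05d}" for i in range(spec.n_test)],
        activities=y_test,
        descriptors=pd.DataFrame(x_test.astype(np.int64), columns=test_names),
    )
    truth = GroundTruth(
        mechanism=spec.mechanism,
        params=params,
        noiseless_train=clean_train,
        noiseless_test=clean_test,
        train_columns=train_names,
        test_columns=test_names,
    )
    return train, test, truth


def generate_aligned(spec: SyntheticSpec) -> tuple[AlignedDataset, GroundTruth]:
    """Generate and vocabulary-align one synthetic target in one call."""
    train, test, truth = generate_dataset(spec)
    return align_vocabularies(train, test), truth


# -- toy molecule fixtures --------------------------------------------------


def toy_molecules() -> dict[str, MolecularGraph]:
    """Small hand-built molecules for fingerprint tests.

    Includes a two-fragment graph (ethane + lone carbon) whose
    cross-fragment pairs sit at infinite topological distance.
    """
    c = lambda h: Atom("C", attached_hydrogens=h)  # noqa: E731
    return {
        "methane": MolecularGraph([c(4)]),
        "propane": MolecularGraph(
            [c(3), c(2), c(3)], [Bond(0, 1), Bond(1, 2)]
        ),
        "ethanol": MolecularGraph(
            [c(3), c(2), Atom("O", attached_hydrogens=1)],
            [Bond(0, 1), Bond(1, 2)],
        ),
        "benzene": MolecularGraph(
            [c(1) for _ in range(6)],
            [Bond(i, (i + 1) % 6, "aromatic") for i in range(6)],
        ),
        "ethane_plus_methane": MolecularGraph(
            [c(3), c(3), c(4)], [Bond(0, 1)]
        ),
    }


#: Hand-enumerated AP fingerprints (max_distance >= diameter) of the toys,
#: keyed by the canonical descriptor text serialization.
EXPECTED_AP_FINGERPRINTS: dict[str, dict[str, int]] = {
    "methane": {},
    "propane": {
        "AP|C(1,0)|1|C(2,0)": 2,
        "AP|C(1,0)|2|C(1,0)": 1,
    },
    "ethanol": {
        "AP|C(1,0)|1|C(2,0)": 1,
        "AP|C(2,0)|1|O(1,0)": 1,
        "AP|C(1,0)|2|O(1,0)": 1,
    },
    "benzene": {
        "AP|C(2,2)|1|C(2,2)": 6,
        "AP|C(2,2)|2|C(2,2)": 6,
        "AP|C(2,2)|3|C(2,2)": 3,
    },
    "ethane_plus_methane": {
        "AP|C(1,0)|1|C(1,0)": 1,
    },
}
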