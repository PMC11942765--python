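"""Fixture polymers and synthetic dataset generators.

Real Tg datasets for polymers are compiled from heterogeneous literature
sources and are not bundled here.  Testing therefore rests on two pillars:

* a fixture set of classic homopolymers whose descriptor values were
  derived by hand from the defining formulas, and
* seeded generators that emulate the statistical structure of such data —
  a couple of dozen inter-correlated descriptors, Tg spanning roughly
  -100..250 Celsius with measurement noise from multi-source averaging, and
  Tg varying smoothly on a low-dimensional non-linear manifold — with the
  generating ground truth stored so recovery can be asserted.

The structure-grammar generator builds actual vinyl repeat units, runs the
real descriptor engine on them, and plants a Tg law with the signs the
correlation analyses are expected to recover: Tg falls with rotational
freedom (N_rot), rises with aromatic content, and falls with the second
backbone index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import FeatureTable
from .descriptors import FEATURE_NAMES, compute_descriptors
from .errors import DataError, PolytgError
from .repeat_unit import parse_repeat_unit

SQ2 = math.sqrt(2.0)
SQ3 = math.sqrt(3.0)
SQ6 = math.sqrt(6.0)


@dataclass
class FixturePolymer:
    name: str
    smiles: str
    expected: dict[str, float]
    source: str = "hand_derived"


def fixture_set() -> list[FixturePolymer]:
    """Classic homopolymers with hand-derived expected descriptor values.

    Every value below was computed by hand from the defining formula
    (degree counts on the closure-augmented graph, Kier-Hall deltas,
    printed group-contribution coefficients, IUPAC atomic weights).
    """
    return [
        FixturePolymer(
            "polyethylene",
            "[*]CC[*]",
            {
                "N": 2, "N_C": 2, "N_H": 4, "N_O": 0,
                "M": 2 * 12.011 + 4 * 1.008,
                "chi0": 2 / SQ2, "chi0v": 2 / SQ2,
                "chi1": 1.0, "chi1v": 1.0,
                "N_rot": 2, "N_SP": 2, "N_K": 0, "Nmv": 0,
                "N_CH2": 2, "BB_index1": 1.0, "BB_index2": 2.0,
            },
        ),
        FixturePolymer(
            "polypropylene",
            "[*]CC(C)[*]",
            {
                "N": 3, "N_H": 6, "M": 3 * 12.011 + 6 * 1.008,
                "chi0": 1 / SQ2 + 1 / SQ3 + 1.0,
                "chi1": 2 / SQ6 + 1 / SQ3,
                "N_rot": 2, "N_SP": 2, "N_K": 0, "Nmv": 0,
            },
        ),
        FixturePolymer(
            "polystyrene",
            "[*]CC([*])c1ccccc1",
            {
                "N": 8, "N_H": 8, "M": 8 * 12.011 + 8 * 1.008,
                "chi0": 6 / SQ2 + 2 / SQ3,
                "chi1": 4 / SQ6 + 1 / 3 + 2.0,
                "chi0v": 1 / SQ2 + 1 / SQ3 + 0.5 + 5 / SQ3,
                "chi1v": 2 / SQ6 + 1 / math.sqrt(12) + 2 / math.sqrt(12)
                + 4 / 3,
                "N_rot": 3, "N_SP": 2, "N_K": 0, "Nmv": 0,
                "N_aromaticring": 1,
            },
        ),
        FixturePolymer(
            "poly(methyl methacrylate)",
            "[*]CC([*])(C)C(=O)OC",
            {
                "N": 7, "N_H": 8, "N_O": 2,
                "M": 5 * 12.011 + 2 * 15.999 + 8 * 1.008,
                "chi0": 2 / SQ2 + 0.5 + 3.0 + 1 / SQ3,
                "chi1": 2 / math.sqrt(8) + 0.5 + 1 / math.sqrt(12)
                + 1 / SQ3 + 1 / SQ6 + 1 / SQ2,
                "N_rot": 4, "N_SP": 2, "N_K": -3, "Nmv": 2,
                "N_ester_n": 0, "N_CH2": 1,
            },
        ),
        FixturePolymer(
            "poly(vinyl chloride)",
            "[*]CC(Cl)[*]",
            {
                "N": 3, "N_H": 3, "M": 2 * 12.011 + 3 * 1.008 + 35.45,
                "chi0": 1 / SQ2 + 1 / SQ3 + 1.0,
                "chi0v": 1 / SQ2 + 1 / SQ3 + math.sqrt(9 / 7),
                "chi1": 2 / SQ6 + 1 / SQ3,
                "N_rot": 2, "N_SP": 2, "N_K": 5, "Nmv": 0,
            },
        ),
        FixturePolymer(
            "poly(ethylene oxide)",
            "[*]CCO[*]",
            {
                "N": 3, "N_H": 4, "N_O": 1,
                "M": 2 * 12.011 + 4 * 1.008 + 15.999,
                "chi0": 3 / SQ2,
                "chi0v": 2 / SQ2 + 1 / SQ6,
                "chi1": 1.5,
                "chi1v": 0.5 + 2 / math.sqrt(12),
                "N_rot": 3, "N_SP": 3, "N_K": -3, "Nmv": 3,
                "N_ether": 1, "N_alkyl_ether": 1, "N_backbone_O": 1,
                "BB_index1": (1 + 1 + 2 / 6) / 3,
            },
        ),
        FixturePolymer(
            "poly(methyl acrylate)",
            "[*]CC([*])C(=O)OC",
            {
                "N": 6, "N_H": 6, "N_O": 2,
                "M": 4 * 12.011 + 2 * 15.999 + 6 * 1.008,
                "chi0": 2 / SQ2 + 2 / SQ3 + 2.0,
                "chi1": 2 / SQ6 + 1 / 3 + 1 / SQ3 + 1 / SQ6 + 1 / SQ2,
                "N_rot": 4, "N_SP": 2, "N_K": -3, "Nmv": 2,
            },
        ),
        FixturePolymer(
            "poly(ethylene terephthalate)",
            "[*]OCCOC(=O)c1ccc(cc1)C(=O)[*]",
            {
                "N": 14, "N_H": 8, "N_O": 4,
                "M": 10 * 12.011 + 4 * 15.999 + 8 * 1.008,
                "chi0": 8 / SQ2 + 4 / SQ3 + 2.0,
                "chi1": 5 * 0.5 + 6 / SQ6 + 2 / SQ3 + 2 / 3,
                "N_rot": 7, "N_SP": 10, "N_K": 0, "Nmv": 4,
                "N_ester_n": 0, "N_ester_c": 2, "N_aromaticring": 1,
                "N_backbone_O": 2, "N_ether": 0, "N_CH2": 2,
            },
        ),
    ]


@dataclass
class SyntheticDataset:
    table: FeatureTable
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# numeric manifold generator
# ---------------------------------------------------------------------------

_N_FEATURES = 22
_MIX_SEED = 20240318  # fixed: the latent->feature maps are part of the design


def _fixed_mixing() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(_MIX_SEED)
    # Near-isometric embedding of the latent sheet: orthonormal rows give an
    # isometry, and each column is then rescaled so every feature has the
    # same variance under the latent distribution.  A model's per-column
    # z-scoring then acts as a near-uniform rescaling and preserves the
    # sheet's geodesic structure.
    Q, _ = np.linalg.qr(rng.normal(size=(_N_FEATURES, 3)))
    W = Q.T
    t_ref = 1.5 * np.pi * rng.uniform(-1.0, 1.0, size=4000)
    ref = np.column_stack(
        [
            np.sin(t_ref),
            rng.uniform(-1.0, 1.0, size=4000),
            np.sign(t_ref) * (np.cos(t_ref) - 1.0),
        ]
    )
    col_sd = (ref @ W).std(axis=0, ddof=1)
    W = W / col_sd * math.sqrt(3 / _N_FEATURES)
    offsets = rng.uniform(1.0, 4.0, size=_N_FEATURES)
    C = np.eye(_N_FEATURES) + 0.3 * rng.normal(size=(_N_FEATURES, _N_FEATURES)) / math.sqrt(_N_FEATURES)
    return W, offsets, C


def generate_manifold_dataset(
    n: int = 150,
    noise_sigma: float = 5.0,
    seed: int = 0,
    manifold: str = "s_curve",
) -> SyntheticDataset:
    """Descriptor-like features on a 2-D latent manifold, Tg affine in the
    latents.

    ``manifold="s_curve"`` bends the latent plane into the classic S-curve
    (a genuinely non-linear embedding whose geodesics Isomap unrolls);
    ``"flat"`` keeps it affine, the limit where Isomap must agree with PCA.
    Tg = 75 + 120 u + 55 v (+ Gaussian noise of sd ``noise_sigma`` C),
    spanning roughly -100..250 C over the latent square.  Feature noise —
    cross-correlated, emulating redundant count-like descriptors — scales
    with ``noise_sigma`` so the noiseless limit is exactly recoverable.
    """
    if n < 20:
        raise DataError("n must be >= 20")
    if manifold not in ("s_curve", "flat"):
        raise DataError(f"unknown manifold kind {manifold!r}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=n)
    v = rng.uniform(-1.0, 1.0, size=n)
    if manifold == "s_curve":
        t = 1.5 * np.pi * u
        coords = np.column_stack(
            [np.sin(t), v, np.sign(t) * (np.cos(t) - 1.0)]
        )
    else:
        coords = np.column_stack([u, v, 0.5 * u + 0.5 * v])

    W, offsets, C = _fixed_mixing()
    X = coords @ W + offsets
    feat_noise_sd = 0.02 * (noise_sigma / 5.0)
    if feat_noise_sd > 0:
        X = X + feat_noise_sd * rng.normal(size=X.shape) @ C

    tg = 75.0 + 120.0 * u + 55.0 * v
    if noise_sigma > 0:
        tg = tg + rng.normal(scale=noise_sigma, size=n)

    ids = [f"s{i:04d}" for i in range(n)]
    cols = [f"x{j + 1:02d}" for j in range(_N_FEATURES)]
    table = FeatureTable(
        ids=ids,
        X=pd.DataFrame(X, columns=cols),
        tg=pd.Series(tg, name="Tg"),
    )
    return SyntheticDataset(
        table=table,
        ground_truth={
            "latents": np.column_stack([u, v]),
            "tg_coefficients": {"intercept": 75.0, "u": 120.0, "v": 55.0},
            "noise_sigma": noise_sigma,
            "manifold": manifold,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# correlated-feature generator for the correlation suite
# ---------------------------------------------------------------------------

def generate_correlation_dataset(
    n: int = 80,
    seed: int = 0,
    noise_sigma: float = 8.0,
    planted_anti_tg: bool = False,
) -> SyntheticDataset:
    """Correlated descriptor-like features with a known Tg law.

    Two latent factors drive Tg; ten features load on them (informative),
    six load on two unrelated factors (correlated nuisance) and six are
    pure noise.  With ``planted_anti_tg`` the last feature is replaced by
    -Tg plus 1% noise — a feature every correlation method must flag with
    sign '-'.  Ground truth records which features are which.
    """
    if n < 20:
        raise DataError("n must be >= 20")
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(n, 4))  # f1,f2 drive Tg; f3,f4 are nuisance
    tg = 75.0 + 60.0 * f[:, 0] + 35.0 * f[:, 1]
    tg = tg + rng.normal(scale=noise_sigma, size=n)

    mix_rng = np.random.default_rng(_MIX_SEED + 1)
    cols, data = [], []
    informative, nuisance, noise_feats = [], [], []
    for j in range(10):
        w = mix_rng.normal(size=2)
        w /= np.linalg.norm(w)
        col = f[:, :2] @ w + 0.35 * rng.normal(size=n)
        name = f"x{j + 1:02d}"
        cols.append(name), data.append(col), informative.append(name)
    for j in range(10, 16):
        w = mix_rng.normal(size=2)
        w /= np.linalg.norm(w)
        col = f[:, 2:] @ w + 0.35 * rng.normal(size=n)
        name = f"x{j + 1:02d}"
        cols.append(name), data.append(col), nuisance.append(name)
    for j in range(16, _N_FEATURES):
        name = f"x{j + 1:02d}"
        cols.append(name), data.append(rng.normal(size=n))
        noise_feats.append(name)

    X = pd.DataFrame(np.column_stack(data), columns=cols)
    planted = None
    if planted_anti_tg:
        planted = cols[-1]
        noise_feats.remove(planted)
        X[planted] = -tg + 0.01 * np.std(tg) * rng.normal(size=n)

    table = FeatureTable(
        ids=[f"c{i:04d}" for i in range(n)],
        X=X,
        tg=pd.Series(tg, name="Tg"),
    )
    return SyntheticDataset(
        table=table,
        ground_truth={
            "informative": informative,
            "nuisance": nuisance,
            "noise": noise_feats,
            "planted_anti_tg": planted,
            "noise_sigma": noise_sigma,
        },
        seed=seed,
    )


def generate_cluster_dataset(
    tg_means: tuple[float, ...] = (50.0, 120.0, 200.0),
    n_per_cluster: int = 20,
    seed: int = 0,
    tg_sd: float = 4.0,
) -> SyntheticDataset:
    """Well-separated feature-space blobs with distinct Tg levels, for the
    k-means cluster-profile check."""
    rng = np.random.default_rng(seed)
    mix_rng = np.random.default_rng(_MIX_SEED + 2)
    centers = mix_rng.normal(scale=8.0, size=(len(tg_means), _N_FEATURES))
    rows, tgs = [], []
    for c, mu in enumerate(tg_means):
        rows.append(
            centers[c] + rng.normal(scale=0.5, size=(n_per_cluster, _N_FEATURES))
        )
        tgs.append(rng.normal(loc=mu, scale=tg_sd, size=n_per_cluster))
    X = np.vstack(rows)
    tg = np.concatenate(tgs)
    table = FeatureTable(
        ids=[f"b{i:04d}" for i in range(len(X))],
        X=pd.DataFrame(
            X, columns=[f"x{j + 1:02d}" for j in range(_N_FEATURES)]
        ),
        tg=pd.Series(tg, name="Tg"),
    )
    return SyntheticDataset(
        table=table,
        ground_truth={
            "tg_means": list(tg_means),
            "labels": np.repeat(np.arange(len(tg_means)), n_per_cluster),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# structure-grammar generator
# ---------------------------------------------------------------------------

_R1_OPTIONS = ["", "C"]
# Side groups span flexibility and oxygen content independently (flexible
# oxygen-free alkyls as well as compact oxygen-rich groups), so N_rot is
# not confounded with the heteroatom counts.
_R2_OPTIONS = [
    "", "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCC(C)C",
    "Cl", "Br", "O", "CO", "OC", "OCC", "COC",
    "c1ccccc1", "Cc1ccccc1", "c1ccc(C)cc1", "CCc1ccccc1", "c1ccc(CC)cc1",
    "C(=O)OC", "C(=O)OCC", "C(=O)OCCC", "OC(=O)C", "C#N", "OCCOC",
]


def grammar_smiles() -> list[str]:
    """All distinct vinyl repeat units [*]CH2-CR1R2[*] in the grammar."""
    seen: dict[frozenset, str] = {}
    out = []
    for r1 in _R1_OPTIONS:
        for r2 in _R2_OPTIONS:
            subs = tuple(s for s in (r1, r2) if s)
            key = tuple(sorted(subs))
            if key in seen:
                continue
            if not subs:
                smi = "[*]CC[*]"
            elif len(subs) == 1:
                smi = f"[*]CC([*]){subs[0]}"
            else:
                smi = f"[*]CC([*])({subs[0]}){subs[1]}"
            seen[key] = smi
            out.append(smi)
    return out


def generate_descriptor_tg_dataset(
    n: int = 60,
    seed: int = 0,
    a: float = 90.0,
    b: float = 30.0,
    c: float = 55.0,
    d: float = 25.0,
    noise_sigma: float = 8.0,
) -> SyntheticDataset:
    """Vinyl repeat units from the fragment grammar, real descriptors, and
    a planted Tg law

        Tg = a - b*N_rot + c*N_aromaticring - d*(BB_index2 - 2) + noise.

    The signs mirror the physics the descriptors encode: rotational freedom
    lowers Tg, aromatic rings raise it.  Every generated SMILES is parsed
    by the real engine; a grammar that emitted an invalid unit would raise.
    """
    if n < 20:
        raise DataError("n must be >= 20")
    rng = np.random.default_rng(seed)
    pool = grammar_smiles()
    picks = rng.choice(len(pool), size=n, replace=True)
    ids, smiles_list, vectors = [], [], []
    for i, p in enumerate(picks):
        smi = pool[p]
        try:
            unit = parse_repeat_unit(smi, f"g{i:04d}")
            vec = compute_descriptors(unit)
        except PolytgError as exc:  # pragma: no cover - grammar is closed
            raise RuntimeError(f"grammar produced invalid unit {smi!r}") from exc
        ids.append(unit.id)
        smiles_list.append(smi)
        vectors.append(vec)

    X = pd.DataFrame([{k: getattr(v, k) for k in FEATURE_NAMES} for v in vectors])
    tg = (
        a
        - b * X["N_rot"].to_numpy()
        + c * X["N_aromaticring"].to_numpy()
        - d * (X["BB_index2"].to_numpy() - 2.0)
        + rng.normal(scale=noise_sigma, size=n)
    )
    table = FeatureTable(ids=ids, X=X, tg=pd.Series(tg, name="Tg"))
    return SyntheticDataset(
        table=table,
        ground_truth={
            "smiles": smiles_list,
            "coefficients": {"a": a, "b": b, "c": c, "d": d},
            "planted_features": ["N_rot", "N_aromaticring", "BB_index2"],
            "noise_sigma": noise_sigma,
        },
        seed=seed,
    )
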