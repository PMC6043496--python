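"""Sequence feature encoders: PAAC, dipeptide composition, and baselines.

The primary pair representation concatenates, per protein, a Type-I pseudo
amino acid composition (20 residue components + lambda sequence-order
correlation tiers computed from five propensity scales) with the 400
ordered-dipeptide frequencies. At lambda = 50 each protein maps to a
470-vector and each (IDP, partner) pair to a 940-vector, IDP first.

Two baseline encoders are included for method comparison: lagged
autocorrelation over arbitrary propensity scales, and conjoint-triad
composition over a 7-class reduced alphabet (with a raw 8000-feature
tripeptide variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidSequenceError
from .scales import PropensityScale, default_paac_scales
from .sequences import AA_TO_INDEX, STANDARD_AA, ProteinSequence

# ---------------------------------------------------------------------------
# configuration and vector containers


@dataclass(eq=False)
class PaacConfig:
    """Parameters of the PAAC encoder.

    lambda_tiers is the maximum correlation tier (tier j correlates residues
    j positions apart), so the minimum encodable sequence length is
    lambda_tiers + 1. weight is the factor w balancing the correlation
    block against the raw composition block.
    """

    lambda_tiers: int = 50
    weight: float = 0.05
    scales: list[PropensityScale] = field(default_factory=default_paac_scales)

    def __post_init__(self) -> None:
        if self.lambda_tiers < 1:
            raise ConfigurationError("lambda_tiers must be >= 1")
        if self.weight < 0:
            raise ConfigurationError("PAAC weight must be non-negative")
        if not self.scales:
            raise ConfigurationError("PAAC requires at least one propensity scale")
        self._theta_matrix: np.ndarray | None = None

    @property
    def min_length(self) -> int:
        return self.lambda_tiers + 1

    def theta_matrix(self) -> np.ndarray:
        """20x20 matrix of pairwise residue correlations.

        Entry (a, b) is the squared-difference correlation function
        Theta(R_a, R_b) = (1/Gamma) sum_k [S_k(R_b) - S_k(R_a)]^2 over the
        Gamma standardized scales. Cached after first use.
        """
        if self._theta_matrix is None:
            mat = np.stack([s.standardize().as_array() for s in self.scales])
            diff = mat[:, None, :] - mat[:, :, None]  # [k, a, b] = S_k(b) - S_k(a)
            self._theta_matrix = (diff**2).mean(axis=0)
        return self._theta_matrix


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding of one sequence."""

    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError(
                f"values length {len(self.values)} != schema length {len(self.schema)}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairVector:
    """Concatenated encoding of an ordered (IDP, partner) pair."""

    values: np.ndarray
    schema: tuple[str, ...]
    idp_id: str
    partner_id: str

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# schemas (lexicographic residue order throughout, so exports are stable)


@lru_cache(maxsize=None)
def dipeptide_schema() -> tuple[str, ...]:
    return tuple(f"dpc:{a}{b}" for a in STANDARD_AA for b in STANDARD_AA)


@lru_cache(maxsize=None)
def paac_schema(lambda_tiers: int) -> tuple[str, ...]:
    return tuple(f"paac:{aa}" for aa in STANDARD_AA) + tuple(
        f"paac:theta_{j}" for j in range(1, lambda_tiers + 1)
    )


@lru_cache(maxsize=None)
def sequence_schema(lambda_tiers: int) -> tuple[str, ...]:
    return paac_schema(lambda_tiers) + dipeptide_schema()


@lru_cache(maxsize=None)
def pair_schema(lambda_tiers: int) -> tuple[str, ...]:
    seq = sequence_schema(lambda_tiers)
    return tuple(f"idp:{n}" for n in seq) + tuple(f"partner:{n}" for n in seq)


def _indices(seq: ProteinSequence) -> np.ndarray:
    return np.fromiter(
        (AA_TO_INDEX[c] for c in seq.residues), dtype=np.intp, count=len(seq)
    )


# ---------------------------------------------------------------------------
# primary encoders


def dipeptide_composition(seq: ProteinSequence) -> FeatureVector:
    """Normalized frequencies of the 400 ordered residue pairs.

    Component XY = count(XY) / (L - 1); the components sum to 1 for any
    sequence of length >= 2. Ordering is lexicographic by first, then
    second residue.
    """
    if len(seq) < 2:
        raise InvalidSequenceError(
            f"sequence {seq.id!r}: dipeptide composition needs >= 2 residues"
        )
    idx = _indices(seq)
    counts = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400).astype(float)
    return FeatureVector(values=counts / (len(seq) - 1), schema=dipeptide_schema())


def paac(seq: ProteinSequence, cfg: PaacConfig | None = None) -> FeatureVector:
    """Type-I pseudo amino acid composition (20 + lambda components).

    Construction: each scale is standardized over the 20 residues; the
    tier-j factor theta_j averages the squared-difference correlation
    Theta between residues j apart; with f_u the raw residue counts and w
    the weight, components are f_u / (L + w*sum(theta)) for the first 20
    and w*theta_j / (L + w*sum(theta)) for the tiers. All 20 + lambda
    components are non-negative and sum to 1.
    """
    cfg = cfg or PaacConfig()
    if len(seq) < cfg.min_length:
        raise InvalidSequenceError(
            f"sequence {seq.id!r}: length {len(seq)} < minimum {cfg.min_length} "
            f"required by lambda = {cfg.lambda_tiers}"
        )
    idx = _indices(seq)
    theta_mat = cfg.theta_matrix()
    thetas = np.array(
        [theta_mat[idx[:-j], idx[j:]].mean() for j in range(1, cfg.lambda_tiers + 1)]
    )
    counts = np.bincount(idx, minlength=20).astype(float)
    denom = counts.sum() + cfg.weight * thetas.sum()
    values = np.concatenate([counts, cfg.weight * thetas]) / denom
    return FeatureVector(values=values, schema=paac_schema(cfg.lambda_tiers))


def encode_sequence(seq: ProteinSequence, cfg: PaacConfig | None = None) -> FeatureVector:
    """Full per-protein encoding: [PAAC | dipeptide], length 20 + lambda + 400."""
    cfg = cfg or PaacConfig()
    p = paac(seq, cfg)
    d = dipeptide_composition(seq)
    return FeatureVector(
        values=np.concatenate([p.values, d.values]),
        schema=sequence_schema(cfg.lambda_tiers),
    )


def encode_pair(
    idp: ProteinSequence, partner: ProteinSequence, cfg: PaacConfig | None = None
) -> PairVector:
    """Ordered pair encoding: the IDP occupies the first half, the partner
    the second. Length 2 * (20 + lambda + 400) = 940 at lambda = 50."""
    cfg = cfg or PaacConfig()
    a = encode_sequence(idp, cfg)
    b = encode_sequence(partner, cfg)
    return PairVector(
        values=np.concatenate([a.values, b.values]),
        schema=pair_schema(cfg.lambda_tiers),
        idp_id=idp.id,
        partner_id=partner.id,
    )


# ---------------------------------------------------------------------------
# baseline encoders (method comparison)


def autocorrelation_features(
    seq: ProteinSequence, scales: list[PropensityScale], max_lag: int
) -> FeatureVector:
    """Lagged autocovariance of propensity-scale profiles along the sequence.

    For scale k and lag d: AC_k(d) = (1/(L-d)) * sum_i (S_k(R_i) - m_k) *
    (S_k(R_{i+d}) - m_k) where m_k is the sequence mean of the profile.
    Scales are standardized over the 20 residues first so magnitudes are
    comparable across scales. Vector length = len(scales) * max_lag.
    """
    if max_lag < 1:
        raise ConfigurationError("max_lag must be >= 1")
    if not scales:
        raise ConfigurationError("autocorrelation requires at least one scale")
    if len(seq) <= max_lag:
        raise InvalidSequenceError(
            f"sequence {seq.id!r}: length {len(seq)} must exceed max_lag {max_lag}"
        )
    idx = _indices(seq)
    out = np.empty(len(scales) * max_lag)
    schema = []
    for k, scale in enumerate(scales):
        profile = scale.standardize().as_array()[idx]
        centered = profile - profile.mean()
        for d in range(1, max_lag + 1):
            out[k * max_lag + d - 1] = centered[:-d] @ centered[d:] / (len(seq) - d)
        schema.extend(f"ac:{scale.name}:lag{d}" for d in range(1, max_lag + 1))
    return FeatureVector(values=out, schema=tuple(schema))


#: Conjoint-triad reduced alphabet: residues grouped by side-chain volume
#: and dipole into 7 classes (Shen et al. convention).
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_CLASS_OF = {aa: i for i, grp in enumerate(CONJOINT_CLASSES) for aa in grp}


def conjoint_triad_features(seq: ProteinSequence, raw_tripeptides: bool = False) -> FeatureVector:
    """Normalized triad composition over a reduced (or raw) alphabet.

    Default: residues map to the 7 conjoint classes and the 343 class
    triads are counted; raw_tripeptides=True instead counts the 8000
    tripeptides over the full alphabet. Frequencies sum to 1.
    """
    if len(seq) < 3:
        raise InvalidSequenceError(
            f"sequence {seq.id!r}: triad composition needs >= 3 residues"
        )
    if raw_tripeptides:
        idx = _indices(seq)
        n = 20
        schema = tuple(
            f"tpc:{a}{b}{c}" for a in STANDARD_AA for b in STANDARD_AA for c in STANDARD_AA
        )
    else:
        idx = np.array([_CLASS_OF[c] for c in seq.residues], dtype=np.intp)
        n = 7
        schema = tuple(
            f"ct:{a}{b}{c}" for a in range(7) for b in range(7) for c in range(7)
        )
    codes = idx[:-2] * n * n + idx[1:-1] * n + idx[2:]
    counts = np.bincount(codes, minlength=n**3).astype(float)
    return FeatureVector(values=counts / (len(seq) - 2), schema=schema)


# ---------------------------------------------------------------------------
# bulk encoding and export


def encode_store(
    store: dict[str, ProteinSequence], cfg: PaacConfig | None = None
) -> pd.DataFrame:
    """Encode every sequence in a store; rows indexed by id, 470 columns."""
    cfg = cfg or PaacConfig()
    rows = {sid: encode_sequence(seq, cfg).values for sid, seq in store.items()}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(sequence_schema(cfg.lambda_tiers))
    )


def pair_matrix(
    pairs: list[tuple[str, str]],
    store: dict[str, ProteinSequence],
    cfg: PaacConfig | None = None,
) -> pd.DataFrame:
    """Encode (idp_id, partner_id) pairs into a 940-column matrix.

    Each unique sequence is encoded once and reused, which is what makes
    dataset-scale featurization cheap.
    """
    cfg = cfg or PaacConfig()
    needed = {sid for pair in pairs for sid in pair}
    missing = sorted(needed - set(store))
    if missing:
        raise KeyError(f"pairs reference ids absent from the sequence store: {missing}")
    per_seq = encode_store({sid: store[sid] for sid in needed}, cfg)
    mat = np.empty((len(pairs), 2 * per_seq.shape[1]))
    for i, (idp_id, partner_id) in enumerate(pairs):
        mat[i, : per_seq.shape[1]] = per_seq.loc[idp_id].to_numpy()
        mat[i, per_seq.shape[1] :] = per_seq.loc[partner_id].to_numpy()
    index = pd.MultiIndex.from_tuples(pairs, names=["idp_id", "partner_id"])
    return pd.DataFrame(mat, index=index, columns=list(pair_schema(cfg.lambda_tiers)))


def write_vectors(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write an encoded matrix as delimited text, id column(s) first."""
    frame.to_csv(path, sep=sep)
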