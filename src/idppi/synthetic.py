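"""Synthetic sequence stores and hub-structured interaction networks.

The generator emulates the two properties of disorder-centric
interactomes that the rest of the pipeline depends on: (i) IDP-like
sequences are compositionally biased toward disorder-promoting residues
(low bulky-hydrophobic, high charged/hydrophilic content), and (ii) IDPs
are hubs — their mean degree far exceeds that of their ordered partners.

An optional *planted rule* makes edges depend on charge complementarity
between the two sequences, a signal that is visible to both the PAAC and
the dipeptide blocks, so end-to-end learnability can be asserted. With
the rule disabled the network carries no sequence-level signal and a
correct pipeline must score at chance — the module's chief purpose is
exactly that leakage guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import POSITIVE, InteractionDataset, InteractionRecord
from .errors import ConfigurationError
from .scales import builtin_scale
from .sequences import STANDARD_AA, ProteinSequence

#: Background residue frequencies (approximately SwissProt-wide), alphabetical.
BACKGROUND_FREQS = {
    "A": 8.25, "C": 1.38, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic interactome.

    disorder_bias tilts IDP-like composition along the (standardized)
    TOP-IDP scale; 0 makes IDPs indistinguishable from partners.
    hub_exponent shapes the truncated power-law IDP degree distribution
    (smaller = heavier tail). charge_sd controls per-sequence net-charge
    variation, rule_strength how sharply the planted rule prefers
    charge-complementary pairs.
    """

    n_idps: int = 30
    n_partners: int = 300
    idp_length_range: tuple[int, int] = (120, 300)
    partner_length_range: tuple[int, int] = (150, 400)
    disorder_bias: float = 0.5
    hub_exponent: float = 1.8
    mean_idp_degree: float = 2.6
    max_idp_degree: int = 12
    max_partner_degree: int = 3
    charge_sd: float = 0.8
    planted_rule: str = "charge_complementarity"
    rule_strength: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_idps < 1 or self.n_partners < 1:
            raise ConfigurationError("need at least one IDP and one partner")
        for lo, hi in (self.idp_length_range, self.partner_length_range):
            if lo < 51 or hi < lo:
                raise ConfigurationError(
                    "length ranges must satisfy 51 <= min <= max (PAAC needs lambda+1 residues)"
                )
        if not 0 <= self.disorder_bias:
            raise ConfigurationError("disorder_bias must be non-negative")
        if self.planted_rule not in ("none", "charge_complementarity"):
            raise ConfigurationError(f"unknown planted_rule {self.planted_rule!r}")
        if self.max_idp_degree > self.n_partners:
            raise ConfigurationError("max_idp_degree cannot exceed n_partners")


def _residue_distribution(bias: float, tilt: float) -> np.ndarray:
    """Background composition re-weighted along disorder propensity and charge."""
    base = np.array([BACKGROUND_FREQS[aa] for aa in STANDARD_AA])
    top_idp = builtin_scale("top-idp").standardize().as_array()
    charge = builtin_scale("net-charge").as_array()
    w = base * np.exp(bias * top_idp + tilt * charge)
    return w / w.sum()


def generate_sequences(cfg: SyntheticConfig) -> dict[str, ProteinSequence]:
    """Draw IDP-like and ordered-like sequences into one store.

    IDP ids are 'IDP###', partner ids 'PRT###' (see :func:`idp_ids_of`).
    Each sequence gets an individual net-charge tilt so per-protein charge
    varies — the raw material for the planted charge-complementarity rule.
    Deterministic under cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    residues = np.array(list(STANDARD_AA))
    store: dict[str, ProteinSequence] = {}

    def draw(name: str, bias: float, tilt: float, length_range: tuple[int, int], kind: str) -> None:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = _residue_distribution(bias, tilt)
        seq = "".join(rng.choice(residues, size=length, p=probs))
        store[name] = ProteinSequence(id=name, residues=seq, description=f"synthetic {kind}")

    for i in range(cfg.n_idps):
        # IDP-like sequences are polyampholytic/polyelectrolytic: every IDP
        # carries a pronounced net charge of random sign, so each has a
        # well-defined complementarity preference under the planted rule
        tilt = float(rng.choice([-1.0, 1.0]) * rng.normal(1.5 * cfg.charge_sd, 0.25 * cfg.charge_sd))
        draw(f"IDP{i:03d}", cfg.disorder_bias, tilt, cfg.idp_length_range, "IDP-like")
    for i in range(cfg.n_partners):
        tilt = float(rng.normal(0.0, cfg.charge_sd))
        draw(f"PRT{i:03d}", 0.0, tilt, cfg.partner_length_range, "ordered-like")
    return store


def idp_ids_of(store: dict[str, ProteinSequence]) -> set[str]:
    """Ids of the IDP-like sequences in a synthetic store."""
    return {sid for sid in store if sid.startswith("IDP")}


def net_charge_per_residue(seq: ProteinSequence) -> float:
    charge = builtin_scale("net-charge").values
    return sum(charge[c] for c in seq.residues) / len(seq)


def generate_network(
    store: dict[str, ProteinSequence], cfg: SyntheticConfig
) -> InteractionDataset:
    """Attach positive edges to the store, IDPs as hubs.

    IDP degrees follow a power law with exponent ``hub_exponent``
    truncated at ``max_idp_degree``; because partners far outnumber IDPs,
    the IDP mean degree exceeds the partner mean degree by roughly
    n_partners/n_idps. Partner degree is capped at ``max_partner_degree``
    (ordered proteins have bounded promiscuity), which also keeps hub
    partners from absorbing a disproportionate share of edges. Under the
    charge-complementarity rule an IDP picks partners with probability
    proportional to exp(rule_strength * z_idp * (-z_partner)), z being
    the z-scored net charge per residue within each group; with
    planted_rule='none' partners are uniform and the network carries no
    sequence signal.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    idps = sorted(idp_ids_of(store))
    partners = sorted(set(store) - set(idps))
    if not idps or not partners:
        raise ConfigurationError("store must contain both IDP-like and partner sequences")

    ks = np.arange(1, cfg.max_idp_degree + 1, dtype=float)
    pk = ks**-cfg.hub_exponent
    pk /= pk.sum()
    degrees = rng.choice(ks.astype(int), size=len(idps), p=pk)
    # pin the edge total to mean_idp_degree * n_idps so network density is a
    # condition of the study, not a lottery over degree draws
    target = int(round(cfg.mean_idp_degree * len(idps)))
    target = min(target, cfg.max_idp_degree * len(idps),
                 cfg.max_partner_degree * len(partners))
    while degrees.sum() > target:
        degrees[degrees.argmax()] -= 1
    while degrees.sum() < target:
        room = np.flatnonzero(degrees < cfg.max_idp_degree)
        degrees[rng.choice(room)] += 1

    def zscores(ids: list[str]) -> np.ndarray:
        q = np.array([net_charge_per_residue(store[s]) for s in ids])
        sd = q.std()
        return (q - q.mean()) / sd if sd > 0 else np.zeros_like(q)

    z_idp = zscores(idps)
    z_par = zscores(partners)

    records: list[InteractionRecord] = []
    partner_load = np.zeros(len(partners), dtype=int)
    for i, idp in enumerate(idps):
        open_slots = partner_load < cfg.max_partner_degree
        if open_slots.sum() < degrees[i]:
            raise ConfigurationError(
                "degree infeasibility: partner capacity exhausted; raise "
                "n_partners or max_partner_degree"
            )
        if cfg.planted_rule == "charge_complementarity":
            logw = cfg.rule_strength * z_idp[i] * (-z_par)
            w = np.where(open_slots, np.exp(logw - logw[open_slots].max()), 0.0)
        else:
            w = open_slots.astype(float)
        probs = w / w.sum()
        chosen = rng.choice(len(partners), size=degrees[i], replace=False, p=probs)
        partner_load[chosen] += 1
        records.extend(
            InteractionRecord(idp, partners[j], POSITIVE) for j in sorted(chosen)
        )
    dataset = InteractionDataset(records, store, set(idps))
    dataset.validate()
    return dataset


def generate(cfg: SyntheticConfig) -> InteractionDataset:
    """Sequences plus network in one call."""
    return generate_network(generate_sequences(cfg), cfg)
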