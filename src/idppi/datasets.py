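"""Interaction datasets: filters, negative sampling, and C2 splits.

The central object is :class:`InteractionDataset`: labelled (IDP, partner)
pairs referencing a sequence store, with the IDP side explicit in every
record. Three concerns live here:

* the sequence-level filters used to build the positive set (minimum
  length, suspicious-name words, 40% identity redundancy reduction);
* negative sampling — *balanced* (degree-preserving, for training, so hub
  proteins cannot dominate learning) and *random* (uniform, for testing at
  realistic class imbalance);
* the component-disjoint C2 split: test pairs share only their IDP with
  the training set, the partner protein is entirely unseen.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from Bio import Align

from .errors import (
    ConfigurationError,
    InfeasibleSamplingError,
    LeakageError,
)
from .sequences import ProteinSequence

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = 1, 0

#: Name words that flag dubious entries in reference proteomes.
DEFAULT_BANNED_WORDS = ("putative", "potential", "uncharacterized")


@dataclass(frozen=True)
class InteractionRecord:
    """One labelled pair; ``idp_id`` is always the disordered side."""

    idp_id: str
    partner_id: str
    label: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.idp_id, self.partner_id)


@dataclass
class InteractionDataset:
    """Labelled pairs plus the sequence store and the set of IDP ids."""

    records: list[InteractionRecord]
    sequence_store: dict[str, ProteinSequence]
    idp_ids: set[str]

    def validate(self) -> None:
        """Enforce structural invariants; raises ValueError on violation."""
        seen: dict[tuple[str, str], int] = {}
        for rec in self.records:
            if rec.idp_id not in self.idp_ids:
                raise ValueError(f"record {rec.key}: {rec.idp_id!r} is not a designated IDP")
            if rec.partner_id in self.idp_ids:
                raise ValueError(
                    f"record {rec.key}: partner {rec.partner_id!r} is itself an IDP; "
                    "pairs must contain exactly one IDP component"
                )
            for sid in rec.key:
                if sid not in self.sequence_store:
                    raise ValueError(f"record {rec.key}: id {sid!r} missing from sequence store")
            if rec.key in seen:
                if seen[rec.key] != rec.label:
                    raise ValueError(f"pair {rec.key} appears with both labels")
                raise ValueError(f"duplicate pair {rec.key} within a label class")
            seen[rec.key] = rec.label

    # -- convenience views ---------------------------------------------------

    def positives(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.label == POSITIVE]

    def negatives(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.label == NEGATIVE]

    def pair_keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self.records}

    def degrees(self, label: int) -> Counter:
        """Appearance count of every protein among records with ``label``."""
        deg: Counter = Counter()
        for r in self.records:
            if r.label == label:
                deg[r.idp_id] += 1
                deg[r.partner_id] += 1
        return deg

    def with_records(self, records: Iterable[InteractionRecord]) -> "InteractionDataset":
        return InteractionDataset(list(records), self.sequence_store, set(self.idp_ids))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the repeated component-disjoint holdout."""

    n_repeats: int = 5
    mode: str = "component_disjoint_C2"
    negative_ratio: float = 1.0
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode != "component_disjoint_C2":
            raise ConfigurationError(f"unknown split mode {self.mode!r}")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.negative_ratio < 1:
            raise ConfigurationError("negative_ratio must be >= 1")


# ---------------------------------------------------------------------------
# sequence-level filters


def filter_sequences(
    store: dict[str, ProteinSequence],
    min_length: int = 50,
    banned_name_words: Iterable[str] = DEFAULT_BANNED_WORDS,
) -> dict[str, ProteinSequence]:
    """Drop short sequences and dubiously-named entries.

    Sequences shorter than ``min_length`` residues are removed (small
    proteins and fragments), as is any sequence whose description contains
    one of the banned words, case-insensitively. Removal counts per rule
    are logged; an empty result is a warning, not an error.
    """
    if not store:
        raise ValueError("empty sequence store")
    words = [w.lower() for w in banned_name_words]
    kept: dict[str, ProteinSequence] = {}
    n_short = n_named = 0
    for sid, seq in store.items():
        if len(seq) < min_length:
            n_short += 1
            continue
        desc = seq.description.lower()
        if any(w in desc for w in words):
            n_named += 1
            continue
        kept[sid] = seq
    logger.info(
        "filter_sequences: removed %d short (< %d aa) and %d banned-name of %d",
        n_short, min_length, n_named, len(store),
    )
    if not kept:
        logger.warning("filter_sequences: no sequences survived the filters")
    return kept


def _identity_aligner() -> Align.PairwiseAligner:
    # Needleman-Wunsch with unit match score; gap open -10, extend -0.5
    # (BLAST-like, documented in the methods note).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment identity: identical positions / alignment length."""
    aligner = _identity_aligner()
    aln = aligner.align(a.residues, b.residues)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def reduce_redundancy(
    store: dict[str, ProteinSequence],
    identity_threshold: float = 0.40,
    cluster_file: str | Path | None = None,
) -> dict[str, ProteinSequence]:
    """Greedy identity clustering; returns one representative per cluster.

    Sequences are visited longest-first (ties by id); a sequence joins the
    first existing cluster whose representative it matches above
    ``identity_threshold``, otherwise it founds a new cluster. Setting
    ``cluster_file`` bypasses internal alignment and takes representatives
    from an externally produced CD-HIT ``.clstr`` file instead, for use at
    proteome scale.
    """
    if not 0 < identity_threshold <= 1:
        raise ConfigurationError("identity_threshold must lie in (0, 1]")
    if cluster_file is not None:
        reps = read_clstr_representatives(cluster_file)
        unknown = reps - set(store)
        if unknown:
            raise ConfigurationError(
                f"cluster file names ids absent from the store: {sorted(unknown)[:5]}"
            )
        return {sid: store[sid] for sid in store if sid in reps}
    order = sorted(store.values(), key=lambda s: (-len(s), s.id))
    representatives: list[ProteinSequence] = []
    for seq in order:
        if not any(
            pairwise_identity(rep, seq) > identity_threshold for rep in representatives
        ):
            representatives.append(seq)
    kept = {r.id for r in representatives}
    logger.info(
        "reduce_redundancy: %d of %d sequences kept at %.0f%% identity",
        len(kept), len(store), identity_threshold * 100,
    )
    return {sid: store[sid] for sid in store if sid in kept}


def read_clstr_representatives(path: str | Path) -> set[str]:
    """Extract representative ids (lines flagged '*') from CD-HIT .clstr output."""
    reps: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(">Cluster"):
            continue
        if line.endswith("*"):
            # e.g. "0	351aa, >P12345... *"
            start = line.index(">") + 1
            reps.add(line[start:].split("...")[0].strip())
    return reps


# ---------------------------------------------------------------------------
# negative sampling


def _forbidden_keys(
    dataset: InteractionDataset, known_positive_filter: set[tuple[str, str]] | None
) -> set[tuple[str, str]]:
    keys = {r.key for r in dataset.records}
    if known_positive_filter:
        keys |= set(known_positive_filter)
    return keys


def sample_negatives(
    positives: InteractionDataset,
    ratio: float = 1.0,
    mode: str = "balanced",
    known_positive_filter: set[tuple[str, str]] | None = None,
    seed: int = 0,
    max_attempts: int | None = None,
    idps: list[str] | None = None,
    partners: list[str] | None = None,
) -> InteractionDataset:
    """Draw non-interacting (IDP, partner) pairs as the negative class.

    balanced mode realizes degree parity: every protein appears among the
    sampled negatives exactly ``ratio`` times as often as among the
    positives, via random pairing of the positive-degree multisets of IDPs
    and partners with rejection of known positives and duplicates
    (conflicting tails are re-shuffled; odd leftovers are repaired by
    swapping against already-accepted pairs). ratio must be a positive
    integer here. random mode draws uniform (IDP, partner) combinations
    until round(ratio * N) negatives exist; the combination universe
    defaults to the dataset's own components but can be widened via the
    ``idps`` / ``partners`` arguments (e.g. to every partner of a test
    partition, not only those carrying a positive record). Both modes
    exclude anything in ``known_positive_filter`` and are deterministic
    under a fixed seed.
    """
    pos = positives.positives()
    if not pos:
        raise ValueError("dataset contains no positive records to balance against")
    forbidden = _forbidden_keys(positives, known_positive_filter)
    rng = np.random.default_rng(seed)
    if mode == "balanced":
        if ratio != int(ratio) or ratio < 1:
            raise ConfigurationError("balanced mode requires an integer ratio >= 1")
        keys = _sample_balanced(pos, int(ratio), forbidden, rng, max_attempts)
    elif mode == "random":
        n_needed = int(round(ratio * len(pos)))
        keys = _sample_random(positives, n_needed, forbidden, rng, idps, partners)
    else:
        raise ConfigurationError(f"unknown sampling mode {mode!r}")
    records = [InteractionRecord(i, p, NEGATIVE) for i, p in keys]
    return positives.with_records(records)


def _sample_balanced(
    pos: list[InteractionRecord],
    ratio: int,
    forbidden: set[tuple[str, str]],
    rng: np.random.Generator,
    max_attempts: int | None,
) -> list[tuple[str, str]]:
    idp_slots = [r.idp_id for r in pos for _ in range(ratio)]
    partner_slots = [r.partner_id for r in pos for _ in range(ratio)]
    if max_attempts is None:
        max_attempts = 100 * len(idp_slots)
    accepted: list[tuple[str, str]] = []
    taken: set[tuple[str, str]] = set()
    rng.shuffle(partner_slots)
    pend_i, pend_p = idp_slots, partner_slots
    attempts = 0
    while pend_i and attempts < max_attempts:
        next_i: list[str] = []
        next_p: list[str] = []
        for i, p in zip(pend_i, pend_p):
            key = (i, p)
            if key in forbidden or key in taken:
                next_i.append(i)
                next_p.append(p)
            else:
                accepted.append(key)
                taken.add(key)
        if len(next_i) == len(pend_i):
            # no progress: the leftover slots conflict among themselves
            # (typical when hub partners concentrate the positive degree);
            # repair by simple swaps, then complete exactly via b-matching
            if not _swap_repair(next_i, next_p, accepted, taken, forbidden):
                _flow_repair(next_i, next_p, accepted, taken, forbidden)
                next_i, next_p = [], []
        rng.shuffle(next_p)
        pend_i, pend_p = next_i, next_p
        attempts += 1
    if pend_i:
        raise InfeasibleSamplingError(
            f"balanced sampling stuck with {len(pend_i)} unmatched slot(s) after "
            f"{attempts} attempts; attainable maximum {len(accepted)} negatives",
            attainable=len(accepted),
        )
    return accepted


def _flow_repair(
    pend_i: list[str],
    pend_p: list[str],
    accepted: list[tuple[str, str]],
    taken: set[tuple[str, str]],
    forbidden: set[tuple[str, str]],
) -> None:
    """Re-solve the full degree-constrained assignment as a max-flow b-matching.

    The greedy phase can strand leftover slots even when a complete
    matching exists (hub partners concentrate degree), so on a stall the
    whole instance is solved exactly: source -> IDP (capacity = slot
    count) -> allowed partner (capacity 1 per distinct pair) -> sink
    (capacity = slot count). Raises InfeasibleSamplingError when even the
    exact solution cannot place every slot.
    """
    import networkx as nx

    idp_count = Counter(pend_i) + Counter(i for i, _ in accepted)
    par_count = Counter(pend_p) + Counter(p for _, p in accepted)
    total = sum(idp_count.values())
    g = nx.DiGraph()
    for i, c in idp_count.items():
        g.add_edge("S", ("i", i), capacity=c)
    for p, c in par_count.items():
        g.add_edge(("p", p), "T", capacity=c)
    for i in idp_count:
        for p in par_count:
            if (i, p) not in forbidden:
                g.add_edge(("i", i), ("p", p), capacity=1)
    flow_value, flow = nx.maximum_flow(g, "S", "T")
    if flow_value < total:
        raise InfeasibleSamplingError(
            f"degree-balanced negative set is infeasible: only {flow_value} of "
            f"{total} slots can be matched without duplicating a pair or "
            "re-creating a known positive",
            attainable=int(flow_value),
        )
    accepted.clear()
    taken.clear()
    for node, targets in flow.items():
        if isinstance(node, tuple) and node[0] == "i":
            for tgt, used in targets.items():
                if used and isinstance(tgt, tuple) and tgt[0] == "p":
                    key = (node[1], tgt[1])
                    accepted.append(key)
                    taken.add(key)
    pend_i.clear()
    pend_p.clear()


def _swap_repair(
    pend_i: list[str],
    pend_p: list[str],
    accepted: list[tuple[str, str]],
    taken: set[tuple[str, str]],
    forbidden: set[tuple[str, str]],
) -> bool:
    """Resolve stuck slots by exchanging partners with an accepted pair."""
    progressed = False
    for idx in range(len(pend_i) - 1, -1, -1):
        i, p = pend_i[idx], pend_p[idx]
        for a_idx, (ai, ap) in enumerate(accepted):
            new1, new2 = (i, ap), (ai, p)
            if (
                new1 not in forbidden and new1 not in taken
                and new2 not in forbidden and new2 not in taken
                and new1 != new2
            ):
                taken.discard((ai, ap))
                accepted[a_idx] = new1
                taken.add(new1)
                accepted.append(new2)
                taken.add(new2)
                del pend_i[idx], pend_p[idx]
                progressed = True
                break
    return progressed


def _sample_random(
    dataset: InteractionDataset,
    n_needed: int,
    forbidden: set[tuple[str, str]],
    rng: np.random.Generator,
    idps: list[str] | None = None,
    partners: list[str] | None = None,
) -> list[tuple[str, str]]:
    if idps is None:
        idps = sorted({r.idp_id for r in dataset.records})
    if partners is None:
        partners = sorted({r.partner_id for r in dataset.records})
    bad = (set(idps) - dataset.idp_ids) | (set(partners) & dataset.idp_ids)
    if bad:
        raise ConfigurationError(
            f"negative universe violates the one-IDP-per-pair contract for ids {sorted(bad)[:5]}"
        )
    allowed = [
        (i, p) for i in idps for p in partners if (i, p) not in forbidden
    ]
    if n_needed > len(allowed):
        raise InfeasibleSamplingError(
            f"requested {n_needed} random negatives but only {len(allowed)} "
            "non-positive combinations exist",
            attainable=len(allowed),
        )
    chosen = rng.choice(len(allowed), size=n_needed, replace=False)
    return [allowed[k] for k in sorted(chosen)]


# ---------------------------------------------------------------------------
# component-disjoint (C2) splitting


class Split(NamedTuple):
    train: InteractionDataset
    test: InteractionDataset
    report: dict


def verify_c2(train: InteractionDataset, test: InteractionDataset) -> dict:
    """Hard leakage check for one split; raises LeakageError on violation.

    Contract: no unordered pair occurs on both sides, and no test partner
    occurs anywhere in training (as either pair component).
    """
    train_components = {c for r in train.records for c in r.key}
    test_partners = {r.partner_id for r in test.records}
    leaked_partners = test_partners & train_components
    shared_pairs = train.pair_keys() & test.pair_keys()
    if leaked_partners:
        raise LeakageError(
            f"test partners present in training pairs: {sorted(leaked_partners)[:5]}"
        )
    if shared_pairs:
        raise LeakageError(f"pairs present on both sides: {sorted(shared_pairs)[:5]}")
    return {
        "n_train": len(train.records),
        "n_test": len(test.records),
        "n_test_partners": len(test_partners),
        "c2_verified": True,
    }


def split_c2(dataset: InteractionDataset, spec: SplitSpec) -> list[Split]:
    """Repeated holdout where test partners never occur in training.

    Partner proteins are partitioned at random into train- and
    test-partners for each repeat; records follow their partner. Every
    test pair's IDP may appear in training — that is the C2 design — but
    its partner is unseen. The partition covers every non-IDP sequence in
    the store (partners without a positive record included, so test-side
    negative sampling has the full candidate universe) and is stratified
    by partner positive-degree, so each repeat's test set carries close to
    test_fraction of the positive pairs instead of a lottery over hub
    partners. Each repeat's report carries the verified leakage check.
    """
    partners = sorted(set(dataset.sequence_store) - dataset.idp_ids)
    if len(partners) < 2:
        raise ValueError("C2 split needs at least 2 distinct partner proteins")
    pos_degree = Counter(r.partner_id for r in dataset.records if r.label == POSITIVE)
    strata: dict[int, list[str]] = {}
    for p in partners:
        strata.setdefault(pos_degree.get(p, 0), []).append(p)
    splits: list[Split] = []
    for rep in range(spec.n_repeats):
        rng = np.random.default_rng([spec.seed, rep])
        test_partners: set[str] = set()
        for _, members in sorted(strata.items()):
            k = int(round(spec.test_fraction * len(members)))
            k = min(max(k, 1 if len(members) > 1 else 0), len(members) - 1)
            if k > 0:
                test_partners |= set(rng.choice(members, size=k, replace=False))
        if not test_partners or len(test_partners) >= len(partners):
            raise ValueError(f"repeat {rep}: degenerate partner partition")
        train_recs = [r for r in dataset.records if r.partner_id not in test_partners]
        test_recs = [r for r in dataset.records if r.partner_id in test_partners]
        if not test_recs:
            raise ValueError(f"repeat {rep}: empty test set (no record uses a test partner)")
        if not train_recs:
            raise ValueError(f"repeat {rep}: empty training set")
        train = dataset.with_records(train_recs)
        test = dataset.with_records(test_recs)
        report = verify_c2(train, test)
        report["repeat"] = rep
        report["seed"] = spec.seed
        # full partner partition (not only partners carrying records), so
        # downstream negative sampling can use the whole test universe
        report["test_partner_ids"] = sorted(test_partners)
        report["train_partner_ids"] = [p for p in partners if p not in test_partners]
        splits.append(Split(train, test, report))
    return splits


# ---------------------------------------------------------------------------
# pair-list I/O (tab-separated: idp_id, partner_id, label, confidence)


def read_pairs(
    path: str | Path,
    sequence_store: dict[str, ProteinSequence],
    idp_ids: set[str],
    dedup: bool = True,
) -> InteractionDataset:
    """Load a pair-list file into a validated dataset.

    Format: tab-separated with header, columns idp_id, partner_id,
    label (0/1) and optional confidence; '#' lines are comments.
    Duplicate pairs are dropped with a warning when ``dedup`` is set.
    """
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str, int]] = set()
    n_dup = 0
    lines = Path(path).read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise ValueError(f"{path}: no pair records found")
    for lineno, line in enumerate(body[1:], start=2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        idp_id, partner_id, label = parts[0], parts[1], int(parts[2])
        conf = float(parts[3]) if len(parts) > 3 and parts[3] != "" else None
        key = (idp_id, partner_id, label)
        if key in seen:
            n_dup += 1
            if dedup:
                continue
        seen.add(key)
        records.append(InteractionRecord(idp_id, partner_id, label, conf))
    if n_dup:
        logger.warning("read_pairs: dropped %d duplicate pair(s) from %s", n_dup, path)
    ds = InteractionDataset(records, sequence_store, set(idp_ids))
    ds.validate()
    return ds


def write_pairs(dataset: InteractionDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("idp_id\tpartner_id\tlabel\tconfidence\n")
        for r in dataset.records:
            conf = "" if r.confidence is None else repr(r.confidence)
            fh.write(f"{r.idp_id}\t{r.partner_id}\t{r.label}\t{conf}\n")


def apply_confidence_cutoff(
    dataset: InteractionDataset, min_confidence: float | None = None
) -> InteractionDataset:
    """Drop positives below an experimental-quality cutoff (default: keep all).

    Reference interactome databases attach quality scores; the exact
    cutoff used upstream is dataset-specific, so it is exposed rather than
    hard-coded.
    """
    if min_confidence is None:
        return dataset
    kept = [
        r
        for r in dataset.records
        if r.label == NEGATIVE or r.confidence is None or r.confidence >= min_confidence
    ]
    return dataset.with_records(kept)
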