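"""Synthetic cohorts with known ground truth.

Emulates the statistical structure of a cancer WGS cohort as seen by a
signature analysis: each tumor carries a subset of active mutational
processes (per-signature marginal presence probabilities, optionally with
hard mutual-exclusivity constraints or co-occurrence odds multipliers
between pairs), Dirichlet relative exposures over the active set, a
negative-binomially distributed mutation burden, and channel counts drawn
multinomially from the resulting mixture profile. Concrete SSM records with
generated flanking context are synthesized from catalogs so that every
record classifies back into exactly the channel it was emitted for,
giving an exact catalog -> records -> catalog round trip.

Contexts are generated sequence, not drawn from a real genome; chromosome
names are synthetic ("chrS1").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import MutationCatalog, MutationKind, MutationRecord
from .channels import BASES, ChannelScheme, channel_labels
from .signature_models import SignatureSet

_REJECTION_CAP = 10_000
CHROMOSOME = "chrS1"


class InfeasibleConstraintError(ValueError):
    """The presence constraint set cannot be satisfied."""


def simulate_signatures(
    n_channels: int,
    n_signatures: int,
    concentration: float = 0.1,
    seed: int = 0,
    max_cosine: float = 0.8,
    labels: list[str] | None = None,
) -> SignatureSet:
    """Draw identifiable signature profiles from a symmetric Dirichlet.

    Columns are rejected until every pairwise cosine similarity is below
    ``max_cosine``, so planted signatures are separable by extraction.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    tries = 0
    while len(cols) < n_signatures:
        cand = rng.dirichlet(np.full(n_channels, concentration))
        ok = all(
            float(cand @ c / (np.linalg.norm(cand) * np.linalg.norm(c))) < max_cosine
            for c in cols
        )
        if ok:
            cols.append(cand)
        tries += 1
        if tries > _REJECTION_CAP:
            raise ValueError(
                "could not draw signatures with pairwise cosine "
                f"< {max_cosine} within {_REJECTION_CAP} attempts"
            )
    ids = [f"SIG{i + 1}" for i in range(n_signatures)]
    if labels is None:
        for scheme in ChannelScheme:
            if scheme.n_channels == n_channels:
                labels = list(channel_labels(scheme))
                break
        else:
            labels = [f"ch{i}" for i in range(n_channels)]
    return SignatureSet(list(labels), ids, np.column_stack(cols), provenance="reference")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reflect a desk-scale breast-cancer-like cohort: ~1,000
    mutations per genome (real WGS breast genomes carry thousands),
    moderately overdispersed burden, sparse Dirichlet exposures.
    """

    n_samples: int
    signatures: SignatureSet
    scheme: ChannelScheme = ChannelScheme.SBS96
    presence_probs: dict[str, float] = field(default_factory=dict)
    exclusive_pairs: list[tuple[str, str]] = field(default_factory=list)
    cooccur_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    dirichlet_alpha: float = 2.0
    burden_mean: float = 1000.0
    burden_dispersion: float = 10.0
    grade_probs: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.15, "G2": 0.45, "G3": 0.4}
    )
    hrd_signature: str | None = None
    seed: int = 0

    def __post_init__(self):
        for sig, p in self.presence_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"presence probability of {sig} outside [0, 1]")
        exset = {frozenset(p) for p in self.exclusive_pairs}
        for pair in self.cooccur_multipliers:
            if frozenset(pair) in exset:
                raise InfeasibleConstraintError(
                    f"pair {pair} is both forced-exclusive and forced-co-occurring"
                )
        for a, b in self.exclusive_pairs:
            if self.presence_probs.get(a, 0.5) >= 1 and self.presence_probs.get(b, 0.5) >= 1:
                raise InfeasibleConstraintError(
                    f"exclusive pair ({a}, {b}) with both marginals at 1 is unsatisfiable"
                )

    def prob_vector(self) -> np.ndarray:
        return np.array(
            [self.presence_probs.get(s, 0.5) for s in self.signatures.signature_ids]
        )


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    presence: pd.DataFrame
    relative_exposures: pd.DataFrame
    burdens: pd.Series
    annotations: pd.DataFrame


def _draw_presence(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Joint presence vector by rejection sampling: independent Bernoulli
    draws, resampled until hard exclusivity holds, >= 1 signature is active,
    and co-occurrence weights accept."""
    ids = spec.signatures.signature_ids
    idx = {s: i for i, s in enumerate(ids)}
    probs = spec.prob_vector()
    excl = [(idx[a], idx[b]) for a, b in spec.exclusive_pairs]
    mult = [(idx[a], idx[b], m) for (a, b), m in spec.cooccur_multipliers.items()]
    wmax = float(np.prod([max(m, 1.0) for *_, m in mult])) if mult else 1.0
    for _ in range(_REJECTION_CAP):
        v = (rng.random(len(ids)) < probs).astype(np.int8)
        if v.sum() == 0:
            continue
        if any(v[i] and v[j] for i, j in excl):
            continue
        if mult:
            w = float(np.prod([m if v[i] and v[j] else 1.0 for i, j, m in mult]))
            if rng.random() >= w / wmax:
                continue
        return v
    first = spec.exclusive_pairs[0] if spec.exclusive_pairs else None
    raise InfeasibleConstraintError(
        f"presence constraints unsatisfied after {_REJECTION_CAP} draws"
        + (f" (check pair {first})" if first else "")
    )


def simulate_cohort(spec: CohortSpec) -> tuple[MutationCatalog, CohortTruth]:
    """Simulate a catalog plus its complete ground truth."""
    rng = np.random.default_rng(spec.seed)
    ids = spec.signatures.signature_ids
    n_sig = len(ids)
    samples = [f"SAMPLE_{i + 1:04d}" for i in range(spec.n_samples)]
    scheme = ChannelScheme(spec.scheme)
    n_channels = spec.signatures.profiles.shape[0]
    if n_channels != scheme.n_channels:
        raise ValueError("signature set does not match the channel scheme")

    presence = np.zeros((spec.n_samples, n_sig), dtype=np.int8)
    exposures = np.zeros((spec.n_samples, n_sig))
    counts = np.zeros((spec.n_samples, n_channels), dtype=np.int64)
    burdens = np.zeros(spec.n_samples, dtype=np.int64)

    disp, mean = spec.burden_dispersion, spec.burden_mean
    p_nb = disp / (disp + mean)
    for i in range(spec.n_samples):
        v = _draw_presence(spec, rng)
        presence[i] = v
        active = np.where(v)[0]
        expo = rng.dirichlet(np.full(active.size, spec.dirichlet_alpha))
        exposures[i, active] = expo
        burden = int(rng.negative_binomial(disp, p_nb))
        burdens[i] = burden
        if burden > 0:
            mixture = spec.signatures.profiles[:, active] @ expo
            counts[i] = rng.multinomial(burden, mixture)

    grades, gprobs = zip(*spec.grade_probs.items())
    grade = rng.choice(grades, size=spec.n_samples, p=np.asarray(gprobs) / sum(gprobs))
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "grade": grade,
            "subtype": "synthetic",
            "hrd_score": np.nan,
            "biallelic_hrd_gene": False,
        }
    ).set_index("sample_id")
    if spec.hrd_signature is not None:
        hrd_active = presence[:, ids.index(spec.hrd_signature)].astype(bool)
        ann["biallelic_hrd_gene"] = hrd_active
        ann["hrd_score"] = np.where(
            hrd_active, rng.uniform(0.5, 1.0, spec.n_samples),
            rng.uniform(0.0, 0.099, spec.n_samples),
        )

    catalog = MutationCatalog(samples, scheme, counts)
    truth = CohortTruth(
        presence=pd.DataFrame(presence, index=samples, columns=ids),
        relative_exposures=pd.DataFrame(exposures, index=samples, columns=ids),
        burdens=pd.Series(burdens, index=samples, name="burden"),
        annotations=ann,
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# channel -> concrete record synthesis
# ---------------------------------------------------------------------------


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n > 0 else ""


def _other_base(rng, *avoid: str) -> str:
    pool = [b for b in BASES if b not in avoid]
    return str(rng.choice(pool))


def _sbs_record(label: str, sample: str, pos: int, rng) -> MutationRecord:
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return MutationRecord(
        sample, CHROMOSOME, pos, ref, alt, MutationKind.SNV,
        context5=_rand_seq(rng, 9) + five, context3=three + _rand_seq(rng, 9),
    )


def _dbs_record(label: str, sample: str, pos: int, rng) -> MutationRecord:
    ref, alt = label.split(">")
    return MutationRecord(
        sample, CHROMOSOME, pos, ref, alt, MutationKind.DNV,
        context5=_rand_seq(rng, 10), context3=_rand_seq(rng, 10),
    )


def _indel_record(label: str, sample: str, pos: int, rng) -> MutationRecord:
    length_s, op, sub, digit_s = label.split(":")
    length, digit = int(length_s), int(digit_s)
    if sub in ("C", "T"):
        base = sub
        stop = _other_base(rng, base)
        left = _other_base(rng, base)
        if op == "Del":
            extra = min(digit + 1, 6) - 1  # run length includes the deleted base
            ref, alt, kind = base, "-", MutationKind.DEL
        else:
            extra = digit
            ref, alt, kind = "-", base, MutationKind.INS
        context5 = _rand_seq(rng, 9) + left
        context3 = base * extra + stop + _rand_seq(rng, 12)
        return MutationRecord(sample, CHROMOSOME, pos, ref, alt, kind, context5, context3)

    unit_len = length if length < 5 else (6 if (sub == "M" and digit >= 5) else 5)
    if sub == "M":
        # deletion at a single copy with flanking microhomology of `digit`
        deleted = _rand_seq(rng, unit_len)
        mh = digit
        stop = _other_base(rng, deleted[mh])
        left = _other_base(rng, deleted[-1])  # no 5' homology
        context5 = _rand_seq(rng, 9) + left
        context3 = deleted[:mh] + stop + _rand_seq(rng, 5 * unit_len)
        return MutationRecord(
            sample, CHROMOSOME, pos, deleted, "-", MutationKind.DEL, context5, context3
        )

    unit = _rand_seq(rng, unit_len)
    if op == "Del":
        copies = min(digit + 1, 6)
        extra = copies - 1
        ref, alt, kind = unit, "-", MutationKind.DEL
    else:
        copies = extra = digit
        ref, alt, kind = "-", unit, MutationKind.INS
    stop = _other_base(rng, unit[0])
    context3 = unit * extra + stop + _rand_seq(rng, 5 * unit_len)
    left = _other_base(rng, unit[-1]) if (op == "Del" and extra == 0) else _rand_seq(rng, 1)
    context5 = _rand_seq(rng, 9) + left
    return MutationRecord(sample, CHROMOSOME, pos, ref, alt, kind, context5, context3)


_BUILDERS = {
    ChannelScheme.SBS96: _sbs_record,
    ChannelScheme.DBS78: _dbs_record,
    ChannelScheme.ID83: _indel_record,
}


def simulate_ssm_records(catalog: MutationCatalog, seed: int = 0) -> list[MutationRecord]:
    """Synthesize one concrete SSM record per counted channel event.

    Alleles and generated flanking context are constructed so each record
    classifies back into exactly its source channel; positions advance on a
    single synthetic chromosome.
    """
    rng = np.random.default_rng(seed)
    build = _BUILDERS[ChannelScheme(catalog.channel_scheme)]
    labels = catalog.channel_labels
    records: list[MutationRecord] = []
    pos = 1000
    for i, sample in enumerate(catalog.sample_ids):
        for j, n in enumerate(catalog.counts[i]):
            for _ in range(int(n)):
                records.append(build(labels[j], sample, pos, rng))
                pos += 1000
    return records
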