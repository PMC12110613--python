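"""Per-sample signature descriptors: grouped contributions, presence calls,
dominant signatures, etiology group assignment and mutation burden.

Signatures are pooled into etiology groups (e.g. APOBEC = SBS2 + SBS13,
HRd = SBS3) before presence and dominance are evaluated, because cohort
summaries are reported at the group level. A sample's *signature group* is
named by its strongest dominant group that is not clock-like (SBS1 "Aging"
or SBS5); samples whose dominants are all clock-like fall into "Others".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import MutationCatalog
from .signature_models import ExposureMatrix

#: Groups considered clock-like when naming a sample's signature group.
CLOCK_LIKE_GROUPS = frozenset({"Aging", "SBS5"})

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "APOBEC": ("SBS2", "SBS13"),
    "HRd": ("SBS3",),
    "HRd-ID": ("ID6",),
    "MMRd": ("SBS26", "SBS44", "DBS7"),
    "BERd": ("SBS30", "SBS36"),
    "ROS": ("SBS18",),
    "NHEJd": ("ID8",),
    "Aging": ("SBS1",),
    "SBS5": ("SBS5",),
    "cAID": ("SBS85",),
    "ncAID": ("SBS9",),
}


@dataclass
class SignatureGroupScheme:
    """Mapping from signature id to etiology group label.

    Signatures absent from the mapping map to themselves (their own group).
    """

    groups: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self):
        seen: dict[str, str] = {}
        for group, members in self.groups.items():
            for sig in members:
                if sig in seen:
                    raise ValueError(f"signature {sig} mapped to both {seen[sig]} and {group}")
                seen[sig] = group
        self._by_signature = seen

    def group_of(self, signature_id: str) -> str:
        return self._by_signature.get(signature_id, signature_id)

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str]]) -> "SignatureGroupScheme":
        return cls({g: tuple(m) for g, m in mapping.items()})


def relative_contributions(
    exposures: ExposureMatrix, grouping: SignatureGroupScheme | None = None
) -> pd.DataFrame:
    """Sum member-signature relative exposures per group (samples x groups)."""
    grouping = grouping or SignatureGroupScheme()
    rel = exposures.rel_frame()
    by_group = rel.T.groupby([grouping.group_of(s) for s in rel.columns]).sum().T
    return by_group


def call_presence(
    contributions: pd.DataFrame,
    burdens: pd.Series,
    threshold: float = 0.05,
    min_mutations: int = 10,
) -> pd.DataFrame:
    """Binary presence: contribution >= threshold (inclusive) AND the
    attributed mutation count (contribution x burden) >= min_mutations."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    b = burdens.reindex(contributions.index).to_numpy(dtype=float)[:, None]
    c = contributions.to_numpy(dtype=float)
    present = (c >= threshold) & (c * b >= min_mutations)
    return pd.DataFrame(
        present.astype(np.int8), index=contributions.index, columns=contributions.columns
    )


def dominant_signatures(contributions: pd.Series) -> tuple[str, str | None]:
    """First and second dominant group of one sample.

    Ties break lexicographically by group label; the second dominant is
    ``None`` when fewer than two groups have nonzero contribution.
    """
    nonzero = contributions[contributions > 0]
    if nonzero.empty:
        raise ValueError("dominance undefined for a sample with no attributed mutations")
    order = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    first = order[0][0]
    second = order[1][0] if len(order) > 1 else None
    return first, second


def assign_signature_group(first: str, second: str | None) -> str:
    """Name the sample's signature group from its two dominant groups.

    Samples whose dominants are all clock-like (SBS1/SBS5) are "Others";
    otherwise the strongest non-clock-like dominant names the group.
    """
    if first is None:
        raise ValueError("first dominant must be defined")
    first_clock = first in CLOCK_LIKE_GROUPS
    second_clock = second is None or second in CLOCK_LIKE_GROUPS
    if first_clock and second_clock:
        return "Others"
    return first if not first_clock else second  # type: ignore[return-value]


def tmb(catalog: MutationCatalog) -> pd.Series:
    """Per-sample mutation totals for the catalog's channel scheme."""
    return catalog.burdens


def sample_profiles(
    exposures: ExposureMatrix,
    burdens: pd.Series,
    grouping: SignatureGroupScheme | None = None,
    threshold: float = 0.05,
    min_mutations: int = 10,
) -> pd.DataFrame:
    """Per-sample profile table: grouped contributions, presence flags,
    dominants, signature group and burden. Zero-burden samples carry
    ``flag_empty`` and no dominance call."""
    grouping = grouping or SignatureGroupScheme()
    contrib = relative_contributions(exposures, grouping)
    presence = call_presence(contrib, burdens, threshold, min_mutations)
    rows = []
    for sample in contrib.index:
        row: dict[str, object] = {"sample_id": sample}
        for g in contrib.columns:
            row[f"contrib_{g}"] = contrib.at[sample, g]
            row[f"present_{g}"] = int(presence.at[sample, g])
        if contrib.loc[sample].sum() > 0:
            first, second = dominant_signatures(contrib.loc[sample])
            row["first_dominant"] = first
            row["second_dominant"] = second if second is not None else ""
            row["signature_group"] = assign_signature_group(first, second)
            row["flag_empty"] = 0
        else:
            row["first_dominant"] = ""
            row["second_dominant"] = ""
            row["signature_group"] = ""
            row["flag_empty"] = 1
        row["tmb"] = int(burdens.get(sample, 0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
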