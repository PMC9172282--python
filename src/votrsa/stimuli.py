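"""Stimulus model and theoretical dissimilarity matrices.

The experiment presents four classes of character-like stimuli in a lexical
decision task:

* **RW** — real words: high-frequency single characters built from two radicals
  (logo-graphemes) at legal positions, with meaning.
* **PW** — pseudowords: legal radical combinations absent from the lexicon;
  unpronounceable and meaningless.
* **FW** — false words: radicals at orthographically illegal positions.
* **SC** — stroke combinations: scrambled strokes with a matched envelope and
  no radical structure.

The logo-grapheme (radical-level) model treats each RW/PW/FW stimulus as a set
of opaque unit tokens; its dissimilarity is one minus the ratio of shared basic
units.  The semantic model applies to RWs only and is one minus the cosine
similarity of word-embedding vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVectorError,
    InvalidStimulusError,
    LookupError_,
    UnsupportedConditionError,
)
from .rdm import RDM

CONDITIONS = ("RW", "PW", "FW", "SC")
#: conditions for which a logo-grapheme model is defined (SC strokes are not
#: logo-graphemes)
LOGO_CONDITIONS = ("RW", "PW", "FW")


@dataclass(frozen=True)
class Stimulus:
    """One character-like item.

    ``logo_graphemes`` are opaque unit tokens (no Unicode decomposition is
    attempted); empty only for SC.  ``frequency`` is occurrences per million,
    defined for RWs and for the donor characters of PWs/FWs, NaN for SC.
    """

    id: str
    condition: str
    logo_graphemes: frozenset[str]
    stroke_count: int
    pixel_fraction: float
    frequency: float = float("nan")

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidStimulusError(f"unknown condition {self.condition!r}")
        if self.condition != "SC" and not self.logo_graphemes:
            raise InvalidStimulusError(
                f"{self.id}: {self.condition} stimulus needs a nonempty logo-grapheme set"
            )
        if self.stroke_count <= 0:
            raise InvalidStimulusError(f"{self.id}: stroke_count must be positive")
        if not 0.0 <= self.pixel_fraction <= 1.0:
            raise InvalidStimulusError(f"{self.id}: pixel_fraction outside [0, 1]")


@dataclass
class StimulusSet:
    """Ordered roster of stimuli; the ordering is the canonical item-indexing
    order used by every RDM built from it."""

    stimuli: list[Stimulus]

    def __post_init__(self):
        ids = [s.id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise InvalidStimulusError("duplicate stimulus ids")

    def __len__(self):
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.stimuli]

    @property
    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for s in self.stimuli:
            counts[s.condition] += 1
        return counts

    def for_condition(self, condition: str) -> "StimulusSet":
        return StimulusSet([s for s in self.stimuli if s.condition == condition])

    def by_id(self, stim_id: str) -> Stimulus:
        for s in self.stimuli:
            if s.id == stim_id:
                return s
        raise LookupError_(f"stimulus id {stim_id!r} not in set")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.stimuli],
                "condition": [s.condition for s in self.stimuli],
                "logo_graphemes": [
                    "|".join(sorted(s.logo_graphemes)) for s in self.stimuli
                ],
                "stroke_count": [s.stroke_count for s in self.stimuli],
                "pixel_fraction": [s.pixel_fraction for s in self.stimuli],
                "frequency": [s.frequency for s in self.stimuli],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        stimuli = []
        for row in df.itertuples(index=False):
            units = str(row.logo_graphemes) if pd.notna(row.logo_graphemes) else ""
            tokens = frozenset(t for t in units.split("|") if t)
            stimuli.append(
                Stimulus(
                    id=str(row.id),
                    condition=str(row.condition),
                    logo_graphemes=tokens,
                    stroke_count=int(row.stroke_count),
                    pixel_fraction=float(row.pixel_fraction),
                    frequency=float(row.frequency) if pd.notna(row.frequency) else float("nan"),
                )
            )
        return cls(stimuli)

    @classmethod
    def from_tsv(cls, path) -> "StimulusSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class EmbeddingTable:
    """Map from stimulus id to a d-dimensional word-embedding vector."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self):
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise InvalidStimulusError(f"mixed embedding dimensions: {dims}")
        for k, v in self.vectors.items():
            self.vectors[k] = np.asarray(v, dtype=float)
            if np.linalg.norm(self.vectors[k]) == 0.0:
                raise DegenerateVectorError(f"all-zero embedding for {k!r}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def __contains__(self, stim_id):
        return stim_id in self.vectors

    def __getitem__(self, stim_id) -> np.ndarray:
        try:
            return self.vectors[stim_id]
        except KeyError:
            raise LookupError_(f"no embedding for id {stim_id!r}") from None

    def to_tsv(self, path) -> None:
        df = pd.DataFrame.from_dict(
            {k: v for k, v in self.vectors.items()}, orient="index"
        )
        df.index.name = "id"
        df.columns = [f"d{i}" for i in range(df.shape[1])]
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls({str(k): row.to_numpy(dtype=float) for k, row in df.iterrows()})


def overlap_ratio(a: frozenset, b: frozenset, convention: str = "dice") -> float:
    """Ratio of shared basic units between two unit sets.

    ``dice`` (default): 2|A∩B| / (|A| + |B|) — equals shared/size for
    equal-size sets, the dominant case of two-radical characters.
    ``jaccard``: |A∩B| / |A∪B|.
    """
    if not a or not b:
        raise InvalidStimulusError("overlap undefined for empty unit sets")
    inter = len(a & b)
    if convention == "dice":
        return 2.0 * inter / (len(a) + len(b))
    if convention == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap convention {convention!r}")


def build_logo_grapheme_rdm(stimuli: StimulusSet, convention: str = "dice") -> RDM:
    """Logo-grapheme RDM: entry(i, j) = 1 − overlap ratio of the unit sets.

    Defined for RW, PW and FW stimuli only; SC items carry no logo-graphemes.
    Values lie in [0, 1]: 0 for identical sets (under Dice), 1 for disjoint.
    """
    conds = {s.condition for s in stimuli}
    if "SC" in conds:
        raise UnsupportedConditionError(
            "logo-grapheme RDMs are defined for RW/PW/FW only, not SC"
        )
    for s in stimuli:
        if not s.logo_graphemes:
            raise InvalidStimulusError(f"{s.id}: empty logo-grapheme set")
    items = list(stimuli)
    n = len(items)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d = 1.0 - overlap_ratio(
                items[i].logo_graphemes, items[j].logo_graphemes, convention
            )
            m[i, j] = m[j, i] = d
    return RDM([s.id for s in items], m, "logo_grapheme")


def build_semantic_rdm(stimuli: StimulusSet, emb: EmbeddingTable) -> RDM:
    """Semantic RDM over RW stimuli: entry(i, j) = 1 − cosine(vᵢ, vⱼ) ∈ [0, 2].

    PWs and FWs are meaningless, so the semantic model exists only for RWs.
    """
    conds = {s.condition for s in stimuli}
    if conds - {"RW"}:
        raise UnsupportedConditionError(
            f"semantic RDM is defined for RW only, got {sorted(conds)}"
        )
    ids = [s.id for s in stimuli]
    vecs = np.stack([emb[i] for i in ids])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateVectorError("zero-norm embedding vector")
    unit = vecs / norms[:, None]
    m = 1.0 - unit @ unit.T
    np.fill_diagonal(m, 0.0)
    m = np.clip((m + m.T) / 2.0, 0.0, 2.0)  # symmetrize away float noise
    return RDM(ids, m, "semantic")


# properties whose condition means the roster is required to match
MATCHED_PROPERTIES = ("stroke_count", "pixel_fraction")


def check_condition_matching(
    stimuli: StimulusSet, tolerance: float = 0.2
) -> pd.DataFrame:
    """Report whether low-level properties are matched across conditions.

    For stroke count and pixel fraction, all four conditions are compared; for
    word frequency, RWs are compared with the donor characters of PWs and FWs.
    The criterion is the maximum pairwise standardized mean difference
    (|SMD| ≤ ``tolerance``, default 0.2); pooled SD of zero with equal means
    counts as a pass.
    """
    df = stimuli.to_frame()
    rows = []

    def smd_report(prop, groups):
        means = {g: df.loc[df.condition == g, prop].mean() for g in groups}
        sds = {g: df.loc[df.condition == g, prop].std(ddof=1) for g in groups}
        worst = 0.0
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                pooled = np.sqrt((sds[a] ** 2 + sds[b] ** 2) / 2.0)
                diff = abs(means[a] - means[b])
                smd = 0.0 if diff == 0 else (np.inf if pooled == 0 else diff / pooled)
                worst = max(worst, smd)
        return means, worst

    for prop in MATCHED_PROPERTIES:
        means, worst = smd_report(prop, list(CONDITIONS))
        rows.append(
            {"property": prop, "max_abs_smd": worst, "passed": worst <= tolerance}
            | {f"mean_{g}": means[g] for g in CONDITIONS}
        )
    means, worst = smd_report("frequency", list(LOGO_CONDITIONS))
    rows.append(
        {"property": "frequency", "max_abs_smd": worst, "passed": worst <= tolerance}
        | {f"mean_{g}": means[g] for g in LOGO_CONDITIONS}
    )
    return pd.DataFrame(rows)
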