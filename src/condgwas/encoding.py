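"""Design-matrix construction for the full genetic model.

Fixed part: population mean, sex block, optional lifestyle cofactor, and per
locus/pair the genetic codings

* additive  xA = 1 (QQ), 0 (Qq), -1 (qq)
* dominance xD = 1 (Qq), 0 (QQ, qq)
* digenic epistasis xAA, xAD, xDA, xDD = elementwise products of the marginals.

Random part: one indicator per ethnic group (e_h, h = 1..4) and, for every
genetic coding, its group-specific incidence column (coding x group
indicator), giving the ae/de/aae/ade/dae/dde interaction structure.

Imputed fractional dosages map continuously: xA = dosage - 1,
xD = 1 - |dosage - 1|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix

ETHNIC_GROUPS = (1, 2, 3, 4)  # 1=E-A, 2=C-A, 3=A-A, 4=H-A
MARGINAL_EFFECTS = ("a", "d")
EPISTASIS_EFFECTS = ("aa", "ad", "da", "dd")
INTERACTION_OF = {
    "a": "ae",
    "d": "de",
    "aa": "aae",
    "ad": "ade",
    "da": "dae",
    "dd": "dde",
}
RANDOM_GROUP_ORDER = ("e", "ae", "de", "aae", "ade", "dae", "dde")


@dataclass
class LocusCoding:
    """Additive/dominance codes for one locus, in cohort subject order."""

    snp_id: str
    xA: np.ndarray
    xD: np.ndarray

    @classmethod
    def from_dosage(cls, snp_id: str, dosage: np.ndarray) -> "LocusCoding":
        dosage = np.asarray(dosage, dtype=float)
        if np.isnan(dosage).any():
            raise ValueError(f"{snp_id}: missing dosages; impute before coding")
        xA = dosage - 1.0
        xD = 1.0 - np.abs(dosage - 1.0)
        return cls(snp_id, xA, xD)


@dataclass
class PairCoding:
    """Digenic epistasis codes: products of the two loci's marginal codes."""

    snp_i: str
    snp_j: str
    xAA: np.ndarray
    xAD: np.ndarray
    xDA: np.ndarray
    xDD: np.ndarray

    @property
    def pair_id(self) -> str:
        return f"{self.snp_i}:{self.snp_j}"


def code_locus(g: GenotypeMatrix, snp_id: str) -> LocusCoding:
    """Code one locus from the genotype matrix (requires imputed dosages)."""
    return LocusCoding.from_dosage(snp_id, g.dosage(snp_id))


def code_pair(ci: LocusCoding, cj: LocusCoding) -> PairCoding:
    if len(ci.xA) != len(cj.xA):
        raise ValueError("locus codings have different lengths")
    return PairCoding(
        ci.snp_id,
        cj.snp_id,
        xAA=ci.xA * cj.xA,
        xAD=ci.xA * cj.xD,
        xDA=ci.xD * cj.xA,
        xDD=ci.xD * cj.xD,
    )


@dataclass
class DesignBundle:
    """Fixed coding columns + random incidence columns + label registry.

    ``random_groups`` maps each variance-component label (e, ae, de, aae,
    ade, dae, dde) to the indices of its columns inside ``random``.
    """

    fixed: np.ndarray
    fixed_labels: list[str]
    random: np.ndarray
    random_labels: list[str]
    random_groups: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.fixed.shape[0]

    @property
    def term_registry(self) -> dict[str, tuple[str, int]]:
        reg = {lab: ("fixed", i) for i, lab in enumerate(self.fixed_labels)}
        for i, lab in enumerate(self.random_labels):
            reg[lab] = ("random", i)
        return reg

    def full_matrix(self) -> np.ndarray:
        if self.random.shape[1] == 0:
            return self.fixed
        return np.hstack([self.fixed, self.random])

    @property
    def full_labels(self) -> list[str]:
        return self.fixed_labels + self.random_labels

    def column(self, label: str) -> np.ndarray:
        kind, i = self.term_registry[label]
        return (self.fixed if kind == "fixed" else self.random)[:, i]

    def columns_for(self, labels) -> np.ndarray:
        return np.column_stack([self.column(lab) for lab in labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.full_matrix(), columns=self.full_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def locus_term_labels(snp_id: str) -> list[str]:
    """All model terms (fixed + interaction) attached to a single locus."""
    labs = [f"a[{snp_id}]", f"d[{snp_id}]"]
    for h in ETHNIC_GROUPS:
        labs.append(f"ae[{snp_id}]_{h}")
    for h in ETHNIC_GROUPS:
        labs.append(f"de[{snp_id}]_{h}")
    return labs


def pair_term_labels(pair_id: str) -> list[str]:
    labs = [f"{eff}[{pair_id}]" for eff in EPISTASIS_EFFECTS]
    for eff in EPISTASIS_EFFECTS:
        for h in ETHNIC_GROUPS:
            labs.append(f"{INTERACTION_OF[eff]}[{pair_id}]_{h}")
    return labs


def build_design(
    cohort: pd.DataFrame,
    codings: list[LocusCoding | PairCoding] | None = None,
    cofactor: str | None = None,
) -> DesignBundle:
    """Assemble the full-model design for a candidate locus/pair set.

    Fixed columns: ``mu``, ``sex``, optionally ``c`` (the named cofactor),
    then per coding its genetic effect columns.  Random columns: the four
    ethnic-group indicators and one incidence column per genetic term per
    group (the coding column zeroed outside the group).
    """
    codings = codings or []
    n = len(cohort)
    eth = cohort["ethnicity"].to_numpy()
    group_ind = {h: (eth == h).astype(float) for h in ETHNIC_GROUPS}

    fixed_cols = [np.ones(n), cohort["sex"].to_numpy(dtype=float)]
    fixed_labels = ["mu", "sex"]
    if cofactor is not None:
        c = cohort[cofactor].to_numpy(dtype=float)
        if np.isnan(c).any():
            raise ValueError(f"cofactor {cofactor!r} has missing values; drop those subjects first")
        if np.ptp(c) == 0:
            raise ValueError(f"cofactor {cofactor!r} is constant")
        fixed_cols.append(c)
        fixed_labels.append("c")

    random_cols = [group_ind[h] for h in ETHNIC_GROUPS]
    random_labels = [f"e_{h}" for h in ETHNIC_GROUPS]
    random_groups: dict[str, list[int]] = {"e": [0, 1, 2, 3]}

    def add_genetic(effect: str, unit_id: str, column: np.ndarray) -> None:
        fixed_cols.append(column)
        fixed_labels.append(f"{effect}[{unit_id}]")
        glab = INTERACTION_OF[effect]
        idxs = random_groups.setdefault(glab, [])
        for h in ETHNIC_GROUPS:
            idxs.append(len(random_cols))
            random_cols.append(column * group_ind[h])
            random_labels.append(f"{glab}[{unit_id}]_{h}")

    for coding in codings:
        if isinstance(coding, LocusCoding):
            add_genetic("a", coding.snp_id, coding.xA)
            add_genetic("d", coding.snp_id, coding.xD)
        elif isinstance(coding, PairCoding):
            add_genetic("aa", coding.pair_id, coding.xAA)
            add_genetic("ad", coding.pair_id, coding.xAD)
            add_genetic("da", coding.pair_id, coding.xDA)
            add_genetic("dd", coding.pair_id, coding.xDD)
        else:
            raise TypeError(f"unsupported coding type: {type(coding)!r}")

    return DesignBundle(
        fixed=np.column_stack(fixed_cols),
        fixed_labels=fixed_labels,
        random=np.column_stack(random_cols) if random_cols else np.empty((n, 0)),
        random_labels=random_labels,
        random_groups=random_groups,
    )
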