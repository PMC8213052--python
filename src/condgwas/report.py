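"""Tabular and graphical outputs plus run provenance.

Tables use one dialect throughout: tab-separated UTF-8 with '.' decimals.
Rounding to presentation precision (2 decimals for heritabilities, 3 for
effect estimates) happens only at the formatting layer; totals columns are
always recomputed from the components at write time, never copied.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .estimation import COMPONENTS, HeritabilityTable


def make_table1(tables: dict[str, HeritabilityTable], round_to: int | None = 2) -> pd.DataFrame:
    """Heritability summary: one row per model, 12 components + recomputed totals."""
    if not tables:
        raise ValueError("need at least one heritability table")
    rows = {}
    for model, t in tables.items():
        s = t.to_series()  # totals recomputed inside HeritabilityTable
        rows[model] = s
    df = pd.DataFrame(rows).T
    df = df[list(COMPONENTS) + ["hT2", "hD+2", "hGE2"]]
    df.index.name = "Model"
    if round_to is not None:
        df = df.round(round_to)
    return df


def make_effect_tables(
    effect_tables: dict[str, pd.DataFrame],
    verdicts: pd.DataFrame | None = None,
    round_effects: int = 3,
    round_h2: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-model effect tables with optional per-cofactor verdict symbols."""
    out = {}
    for model, df in effect_tables.items():
        df = df.copy()
        if len(df):
            df["estimate"] = df["estimate"].round(round_effects)
            df["se"] = df["se"].round(round_effects)
            df["neg_log10_p_ew"] = df["neg_log10_p_ew"].round(round_effects)
            df["h2_percent"] = df["h2_percent"].round(round_h2)
        if verdicts is not None and len(df) and len(verdicts):
            sym = verdicts.pivot_table(
                index=["unit", "effect"], columns="cofactor", values="symbol", aggfunc="first"
            )
            df = df.merge(sym, left_on=["unit", "effect"], right_index=True, how="left")
        out[model] = df
    return out


def read_effect_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def plot_architecture(
    scan_frames: dict[str, pd.DataFrame], threshold: float = 5.0, path=None
):
    """Dot-and-line genetic-architecture chart across models.

    One panel column; per model, dots mark single loci whose -log10 P_EW
    clears ``threshold`` and vertical lines join the members of significant
    epistatic pairs.
    """
    fig, ax = plt.subplots(figsize=(8, 5))
    units: list[str] = []
    for frame in scan_frames.values():
        for u in frame.loc[frame["neg_log10_p_ew"] > threshold, "unit"]:
            for part in str(u).split(":"):
                if part not in units:
                    units.append(part)
    ypos = {u: i for i, u in enumerate(units)}
    n_lines = 0
    for xm, (model, frame) in enumerate(scan_frames.items()):
        sig = frame[frame["neg_log10_p_ew"] > threshold]
        for u in sig["unit"]:
            parts = str(u).split(":")
            if len(parts) == 1:
                ax.plot(xm, ypos[parts[0]], "o", color="tab:red")
            else:
                y0, y1 = ypos[parts[0]], ypos[parts[1]]
                ax.plot([xm, xm], [y0, y1], "-", color="tab:green")
                ax.plot([xm, xm], [y0, y1], "s", color="tab:green", ms=4)
                n_lines += 1
    ax.set_xticks(range(len(scan_frames)))
    ax.set_xticklabels(list(scan_frames), rotation=30, ha="right")
    ax.set_yticks(range(len(units)))
    ax.set_yticklabels(units, fontsize=7)
    ax.set_ylabel("locus")
    ax.set_title(f"Significant units (-log10 P_EW > {threshold:g})")
    ax.plot([], [], "o", color="tab:red", label="single-locus effect")
    ax.plot([], [], "-s", color="tab:green", label="epistatic pair")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig, n_lines


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    config: dict
    seed: int
    input_hashes: dict[str, str] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    package_version: str = "0.1.0"

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def add_input(self, name: str, path) -> None:
        self.input_hashes[name] = self.hash_file(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def matches(self, other: "RunManifest") -> bool:
        return (
            self.command == other.command
            and self.config == other.config
            and self.seed == other.seed
            and self.input_hashes == other.input_hashes
        )
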