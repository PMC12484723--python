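"""Multiplexed abundance tables to per-analyte covalent occupancies.

A pulldown-proteomics experiment quantifies, per multiplex channel, how much
of each protein the affinity probe still captured after inhibitor
pre-incubation. Two control channels anchor the scale: the DMSO control
(no inhibitor, full probe labeling, 0% inhibitor occupancy) and the
saturation control (inhibitor at saturating dose/time so every competable
pocket is pre-occupied, defining the background signal floor). For analyte
intensity A in a treated channel,

    probe fraction = (A - A_sat) / (A_dmso - A_sat)
    occupancy      = 1 - probe fraction

Before control normalization, channel-to-channel pulldown variation is
removed by dividing every channel by an internal reference analyte that is
enriched equally everywhere (the endogenous biotinylated carboxylase ACC1 in
typical streptavidin pulldowns); if the reference is absent, total-intensity
normalization is the fallback.

Occupancies outside [0, 1] (noise around the controls) are clamped with QC
flags; analytes whose DMSO and saturation intensities do not separate carry
no competable signal and are flagged unquantifiable. Ranking analytes by
-log2(A_sat/A_dmso) orders the proteome by competable enrichment, i.e. by
how strongly the inhibitor engages each protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelDesign",
    "ExperimentDesign",
    "normalize_reference",
    "to_occupancy",
    "rank_offtargets",
    "DEFAULT_REFERENCE",
]

DEFAULT_REFERENCE = "ACC1"
ROLES = ("treated", "dmso_control", "saturation_control")


@dataclass(frozen=True)
class ChannelDesign:
    """One multiplex channel: its role and, if treated, its (conc, time)."""

    channel: str
    role: str
    conc: Optional[float] = None  # M, treated channels only
    time: Optional[float] = None  # s, treated channels only
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"channel {self.channel!r}: unknown role {self.role!r}")
        if self.role == "treated":
            if self.conc is None or self.conc < 0:
                raise ValueError(f"treated channel {self.channel!r} needs conc >= 0")
            if self.time is None or self.time < 0:
                raise ValueError(f"treated channel {self.channel!r} needs time >= 0")


class ExperimentDesign:
    """A validated set of channels: per replicate, exactly one control pair."""

    def __init__(self, channels: Sequence[ChannelDesign]):
        labels = [c.channel for c in channels]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels in design")
        self.channels = list(channels)
        for rep, group in self._by_replicate().items():
            for role in ("dmso_control", "saturation_control"):
                k = sum(1 for c in group if c.role == role)
                if k != 1:
                    raise ValueError(
                        f"replicate {rep!r} must have exactly one {role}, found {k}"
                    )

    def _by_replicate(self) -> dict[str, list[ChannelDesign]]:
        out: dict[str, list[ChannelDesign]] = {}
        for c in self.channels:
            out.setdefault(c.replicate, []).append(c)
        return out

    @property
    def labels(self) -> list[str]:
        return [c.channel for c in self.channels]

    def replicates(self):
        return self._by_replicate().items()


def normalize_reference(
    table: pd.DataFrame,
    ref_id: str = DEFAULT_REFERENCE,
    fallback_total: bool = True,
) -> pd.DataFrame:
    """Divide every channel by its reference-analyte intensity.

    The reference row becomes all ones. If the reference is absent (or zero
    in some channel) and ``fallback_total`` is set, channels are divided by
    their column sums instead, with a warning; otherwise this is an error.
    """
    if ref_id in table.index:
        ref = table.loc[ref_id].astype(float)
        if (ref > 0).all():
            return table.astype(float).div(ref, axis=1)
        problem = f"reference {ref_id!r} has nonpositive intensity in some channel"
    else:
        problem = f"reference {ref_id!r} not found in table"
    if not fallback_total:
        raise ValueError(problem)
    warnings.warn(f"{problem}; falling back to total-intensity normalization")
    sums = table.sum(axis=0).astype(float)
    if (sums <= 0).any():
        raise ValueError("total-intensity fallback impossible: zero column sum")
    return table.astype(float).div(sums, axis=1)


def to_occupancy(
    table: pd.DataFrame,
    design: ExperimentDesign | Sequence[ChannelDesign],
    psm_counts: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Control-normalize a (reference-normalized) table into occupancies.

    Returns a tidy frame with columns ``analyte, conc, time, replicate,
    occupancy, qc_flags``. Flags: ``clamped_low``/``clamped_high`` for
    occupancies pushed back into [0, 1], ``unquantifiable`` when
    A_dmso - A_sat <= 0 (those analytes carry no occupancy values), and
    ``low_evidence`` for single-PSM analytes when counts are provided.
    """
    if not isinstance(design, ExperimentDesign):
        design = ExperimentDesign(design)
    missing = [c for c in design.labels if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing design channels: {missing}")

    rows = []
    for rep, group in design.replicates():
        dmso = next(c for c in group if c.role == "dmso_control")
        sat = next(c for c in group if c.role == "saturation_control")
        treated = [c for c in group if c.role == "treated"]
        a_dmso = table[dmso.channel].astype(float)
        a_sat = table[sat.channel].astype(float)
        span = a_dmso - a_sat
        for analyte in table.index:
            base_flags = []
            if psm_counts is not None and psm_counts.get(analyte, 2) <= 1:
                base_flags.append("low_evidence")
            if span[analyte] <= 0:
                rows.append({
                    "analyte": analyte, "conc": np.nan, "time": np.nan,
                    "replicate": rep, "occupancy": np.nan,
                    "qc_flags": ";".join(base_flags + ["unquantifiable"]),
                })
                continue
            for ch in treated:
                probe_frac = (table.at[analyte, ch.channel] - a_sat[analyte]) / span[analyte]
                occ = 1.0 - probe_frac
                flags = list(base_flags)
                if occ < 0.0:
                    occ = 0.0
                    flags.append("clamped_low")
                elif occ > 1.0:
                    occ = 1.0
                    flags.append("clamped_high")
                rows.append({
                    "analyte": analyte, "conc": ch.conc, "time": ch.time,
                    "replicate": rep, "occupancy": occ,
                    "qc_flags": ";".join(flags),
                })
    return pd.DataFrame(rows)


def rank_offtargets(
    table: pd.DataFrame,
    design: ExperimentDesign | Sequence[ChannelDesign],
    replicate: Optional[str] = None,
) -> pd.DataFrame:
    """Rank analytes by competable enrichment, score = -log2(A_sat/A_dmso).

    High scores mean the saturating inhibitor displaced most of the probe
    signal — the hallmark of genuine on/off-targets. Analytes with a
    nonpositive intensity in either control are excluded with a flag. With
    several replicates the per-replicate scores are averaged unless one
    replicate is requested.
    """
    if not isinstance(design, ExperimentDesign):
        design = ExperimentDesign(design)
    reps = dict(design.replicates())
    if replicate is not None:
        reps = {replicate: reps[replicate]}
    scores = []
    excluded = set()
    for rep, group in reps.items():
        dmso = next(c for c in group if c.role == "dmso_control").channel
        sat = next(c for c in group if c.role == "saturation_control").channel
        a_dmso = table[dmso].astype(float)
        a_sat = table[sat].astype(float)
        bad = (a_dmso <= 0) | (a_sat <= 0)
        excluded |= set(table.index[bad])
        s = -np.log2(a_sat.where(~bad) / a_dmso.where(~bad))
        scores.append(s)
    score = pd.concat(scores, axis=1).mean(axis=1)
    out = pd.DataFrame({"analyte": table.index, "score": score.values})
    out["flag"] = ["nonpositive_intensity" if a in excluded else "" for a in out["analyte"]]
    out = out.sort_values("score", ascending=False, na_position="last")
    return out.reset_index(drop=True)
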