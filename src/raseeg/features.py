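"""Cognitive/affective EEG features computed per window.

Each feature is a function of the baseline-normalized channel-band powers
of one window: a regional mean, a ratio of regional means, or the
left-to-right hemisphere asymmetry ratio. The built-in registry holds the
16 unique definitions implied by the published electrode sets (the source
counts "15 distinct features"; de-duplicating its table yields 16 — the
``paper15`` preset lets a user drop any one once the intended exclusion is
known). No construct-validity claim is made: these are the formulas only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import REGIONS
from .windowing import BandPowerTable

log = logging.getLogger(__name__)

_G = REGIONS["global"]


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    categories: tuple[str, ...]
    kind: str                                # regional_mean | ratio | asymmetry_ratio
    numerator: tuple[tuple[str, str], ...]   # (channel, band) terms
    denominator: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.kind not in ("regional_mean", "ratio", "asymmetry_ratio"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.kind != "regional_mean") != bool(self.denominator):
            raise ValueError(f"{self.name}: denominator must be non-empty "
                             "iff kind is a ratio")

    def channels(self) -> set[str]:
        return {ch for ch, _ in self.numerator + self.denominator}


def _terms(channels, band) -> tuple[tuple[str, str], ...]:
    return tuple((ch, band) for ch in channels)


def builtin_features() -> list[FeatureDefinition]:
    """The 16 unique feature definitions, electrode sets as published."""
    return [
        FeatureDefinition(
            "global_beta_to_alpha_theta_ratio", ("attention",), "ratio",
            _terms(_G, "beta"), _terms(_G, "alpha") + _terms(_G, "theta")),
        FeatureDefinition("occipital_beta", ("attention",), "regional_mean",
                          _terms(REGIONS["occipital"], "beta")),
        FeatureDefinition("occipital_delta", ("attention",), "regional_mean",
                          _terms(REGIONS["occipital"], "delta")),
        FeatureDefinition("occipital_theta", ("attention",), "regional_mean",
                          _terms(REGIONS["occipital"], "theta")),
        FeatureDefinition("frontal_theta",
                          ("attention", "cognitive_load", "cognitive_fatigue"),
                          "regional_mean", _terms(REGIONS["frontal"], "theta")),
        FeatureDefinition("global_gamma", ("attention", "valence", "arousal"),
                          "regional_mean", _terms(_G, "gamma")),
        FeatureDefinition("frontal_alpha", ("cognitive_load",),
                          "regional_mean", _terms(REGIONS["frontal"], "alpha")),
        FeatureDefinition("parietal_alpha", ("cognitive_load",),
                          "regional_mean", _terms(REGIONS["parietal"], "alpha")),
        FeatureDefinition("global_alpha", ("cognitive_fatigue", "valence"),
                          "regional_mean", _terms(_G, "alpha")),
        FeatureDefinition("occipital_alpha", ("cognitive_fatigue",),
                          "regional_mean", _terms(REGIONS["occipital"], "alpha")),
        FeatureDefinition("fz_theta_to_alpha_ratio", ("cognitive_fatigue",),
                          "ratio", (("Fz", "theta"),), (("Fz", "alpha"),)),
        FeatureDefinition("alpha_asymmetry", ("valence",), "asymmetry_ratio",
                          _terms(REGIONS["left"], "alpha"),
                          _terms(REGIONS["right"], "alpha")),
        FeatureDefinition("global_beta",
                          ("valence", "arousal", "error_recognition"),
                          "regional_mean", _terms(_G, "beta")),
        FeatureDefinition("global_theta", ("arousal", "error_recognition"),
                          "regional_mean", _terms(_G, "theta")),
        FeatureDefinition("global_alpha_to_beta_ratio", ("dominance",),
                          "ratio", _terms(_G, "alpha"), _terms(_G, "beta")),
        FeatureDefinition("parietal_beta", ("dominance",), "regional_mean",
                          _terms(REGIONS["parietal"], "beta")),
    ]


def paper15_features(drop: str = "occipital_theta") -> list[FeatureDefinition]:
    """15-feature preset: the 16 built-ins minus ``drop``. Which feature the
    published count excluded is not determinable, so the choice is explicit."""
    defs = [d for d in builtin_features() if d.name != drop]
    if len(defs) != 15:
        raise ValueError(f"unknown feature {drop!r}")
    return defs


def registry_json(defs=None) -> str:
    defs = builtin_features() if defs is None else defs
    return json.dumps([{
        "name": d.name, "categories": list(d.categories), "kind": d.kind,
        "numerator": [list(t) for t in d.numerator],
        "denominator": [list(t) for t in d.denominator]} for d in defs],
        indent=1)


# ----------------------------------------------------------------------
@dataclass
class FeatureTable:
    """Per-window feature values, rows aligned with the source power table."""

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def error(self) -> pd.Series:
        return self.meta["error"]

    def to_csv(self, path) -> None:
        self.meta.join(self.values).to_csv(path)


def compute_features(table: BandPowerTable,
                     defs: list[FeatureDefinition] | None = None
                     ) -> FeatureTable:
    """Evaluate feature definitions on a baseline-normalized power table.

    regional_mean: arithmetic mean of the member relative powers.
    ratio / asymmetry_ratio: each side is aggregated per band as the channel
    mean and summed across its bands, then the two sides divided — so the
    beta:(alpha+theta) ratio on a uniform table of value p is p/(p+p) = 1/2.
    A non-positive denominator yields NaN (guards corrupted tables; it
    cannot arise from valid RMS ratios) and is counted in the log.
    """
    if not table.normalized:
        raise ValueError("features are defined on baseline-normalized powers")
    defs = builtin_features() if defs is None else defs
    missing: dict[str, set[str]] = {}
    for d in defs:
        absent = d.channels() - set(table.channels)
        if absent:
            missing[d.name] = absent
    if missing:
        raise ValueError(f"montage missing channels for feature(s): {missing}")

    def _aggregate(terms):
        """Channel mean within each band, summed across the bands."""
        by_band: dict[str, list[str]] = {}
        for c, b in terms:
            by_band.setdefault(b, []).append(f"{c}_{b}")
        parts = [table.values[cols_].mean(axis=1)
                 for cols_ in by_band.values()]
        return sum(parts[1:], parts[0])

    cols = {}
    n_nan = 0
    for d in defs:
        num = _aggregate(d.numerator)
        if d.kind == "regional_mean":
            cols[d.name] = num
        else:
            den = _aggregate(d.denominator)
            bad = den <= 0
            if bad.any():
                n_nan += int(bad.sum())
                den = den.where(~bad)
            cols[d.name] = num / den
    if n_nan:
        log.warning("compute_features: %d window(s) with non-positive "
                    "denominator set to NaN", n_nan)
    values = pd.DataFrame(cols, index=table.values.index)
    return FeatureTable(values, table.meta.copy())
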