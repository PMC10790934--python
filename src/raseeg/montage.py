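"""Electrode montage handling for the international 10-20 system.

The analysis operates on the 19-channel 10-20 montage. Odd-numbered labels
sit over the left hemisphere, even-numbered over the right, and ``z`` labels
on the midline. Regional groupings below follow the electrode sets used by
the cognitive/affective feature definitions.
"""

from __future__ import annotations

MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Regional electrode sets. ``left``/``right`` are the hemisphere splits used
#: by the alpha-asymmetry feature (midline electrodes belong to neither).
REGIONS: dict[str, tuple[str, ...]] = {
    "occipital": ("O1", "O2"),
    "parietal": ("P3", "P4", "Pz", "P7", "P8"),
    "frontal": ("F4", "Fz", "F3"),
    "left": ("F7", "Fp1", "F3", "C3", "P7", "T3", "P3", "O1"),
    "right": ("Fp2", "F8", "F4", "P8", "P4", "O2", "C4", "T4"),
    "global": MONTAGE_1020,
    "all": MONTAGE_1020,
}


def resolve_channels(spec, montage=MONTAGE_1020) -> tuple[str, ...]:
    """Resolve a channel specifier to concrete electrode labels.

    ``spec`` may be a single label (``"O1"``), a ``+``-joined list
    (``"O1+O2"``), a region keyword (``"occipital"``, ``"left"``, ...), or an
    iterable of labels. Raises ``ValueError`` for labels absent from
    ``montage``.
    """
    montage = tuple(montage)
    if isinstance(spec, str):
        key = spec.lower()
        if key in REGIONS:
            chans = [c for c in REGIONS[key] if c in montage]
            if not chans:
                raise ValueError(f"region {spec!r} has no channels in montage")
            return tuple(chans)
        parts = [p.strip() for p in spec.split("+")] if "+" in spec else [spec]
    else:
        parts = list(spec)
    missing = [p for p in parts if p not in montage]
    if missing:
        raise ValueError(f"channel(s) not in montage: {missing}")
    return tuple(parts)
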