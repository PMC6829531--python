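"""Curated complex I (NADH:ubiquinone oxidoreductase) module membership.

Hand-curated assignment of human CI subunit gene symbols to the three
functional modules: the NADH-oxidizing N-module, the ubiquinone-reducing
Q-module, and the proton-pumping P-module (membrane arm). The split
follows the consensus structural assignments in the literature; a few
accessory subunits sit at module interfaces and any such assignment is a
judgment call. Treat these lists as a curated resource, not a measured
one, and override them with your own gene sets where needed.
"""

from __future__ import annotations

CI_MODULES: dict[str, tuple[str, ...]] = {
    "N": (
        "NDUFV1",
        "NDUFV2",
        "NDUFV3",
        "NDUFS1",
        "NDUFS4",
        "NDUFS6",
        "NDUFA2",
        "NDUFA6",
        "NDUFA7",
        "NDUFA12",
        "NDUFAB1",
    ),
    "Q": (
        "NDUFS2",
        "NDUFS3",
        "NDUFS7",
        "NDUFS8",
        "NDUFA5",
        "NDUFA9",
        "NDUFA3",
        "NDUFA8",
        "NDUFA13",
    ),
    "P": (
        "MT-ND1",
        "MT-ND2",
        "MT-ND3",
        "MT-ND4",
        "MT-ND4L",
        "MT-ND5",
        "MT-ND6",
        "NDUFA1",
        "NDUFA10",
        "NDUFA11",
        "NDUFB1",
        "NDUFB2",
        "NDUFB3",
        "NDUFB4",
        "NDUFB5",
        "NDUFB6",
        "NDUFB7",
        "NDUFB8",
        "NDUFB9",
        "NDUFB10",
        "NDUFB11",
        "NDUFC1",
        "NDUFC2",
        "NDUFS5",
    ),
}

ALL_CI_SUBUNITS: tuple[str, ...] = tuple(
    g for members in CI_MODULES.values() for g in members
)
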