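"""Synthetic fixtures with known ground truth.

Two generators:

* :func:`make_bridge_structure` emits a toy PDB in which two 4Fe-4S
  cluster mimics are bridged by a single residue whose side chain closes
  the gap (a valine's CG1/CG2, or an aspartate's CB/CG), next to a
  deliberately weaker backbone decoy route. Every coordinate is placed
  on a 0.001 Angstrom grid, the intended bond topology is explicit, and
  the dominant pathway coupling is evaluated analytically from a fixed
  inventory of designed routes - so the full analysis pipeline can be
  checked against an exact product of decay factors, both for the wild
  type and after side-chain truncation.

* :func:`make_omics_table` emits a log-normal abundance table with
  grouped replicates, planted multiplicative effects, replicate noise at
  a stated coefficient of variation, and abundance-dependent dropout,
  together with a truth table of every planted effect.

All randomness flows from the single seed stored in each design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .ci_modules import CI_MODULES
from .omics import AbundanceTable
from .pathways import DecayModel, DEFAULT_DECAY

# ---------------------------------------------------------------------------
# structure fixture


@dataclass(frozen=True)
class BridgeDesign:
    """Geometry knobs for the two-cluster bridge fixture.

    ``bridge_res`` selects the bridging residue (VAL or ASP). ``jitter``
    scales a seed-driven shift (in [0, jitter] Angstrom) of the acceptor
    cluster and the distal side-chain atom along the inter-cluster axis,
    so that batches of structures differ while preserving the designed
    route ordering. The decoy is a two-glycine backbone route that is
    strictly weaker than the side-chain bridge by construction.
    """

    bridge_res: str = "VAL"
    jitter: float = 0.4
    seed: int = 0
    decay: DecayModel = field(default_factory=DecayModel)


@dataclass
class BridgeTruth:
    """Generator bookkeeping for one bridge structure."""

    n_atoms: int
    inter_cluster_min_distance: float
    wt_route: list[str]
    wt_steps: list[tuple[str, str, float, float]]  # (kind, atoms, distance, epsilon)
    T_wt: float
    mutations: dict[str, dict]  # mutation string -> {route, steps, T, rate_ratio}
    cofactors: dict[str, str]
    bridge_site: tuple[str, int]


def _cluster_atoms(center: np.ndarray, serial0: int) -> list[tuple]:
    """4Fe-4S cubane mimic: Fe on even-parity cube corners, S on odd."""
    s = 1.1
    atoms = []
    fe_i = s_i = 0
    for ix in (1, -1):
        for iy in (1, -1):
            for iz in (1, -1):
                pos = center + s * np.array([ix, iy, iz])
                if ix * iy * iz > 0:
                    fe_i += 1
                    atoms.append((f"FE{fe_i}", "FE", pos))
                else:
                    s_i += 1
                    atoms.append((f"S{s_i}", "S", pos))
    return [(serial0 + i, name, el, pos) for i, (name, el, pos) in enumerate(atoms)]


def _pair_step(el_i: str, pos_i, el_j: str, pos_j, bonded: bool,
               same_residue: bool, decay: DecayModel,
               space_cutoff: float = 6.0) -> tuple[str, float, float] | None:
    """Analytic step classification mirroring the design rules."""
    d = float(np.linalg.norm(np.asarray(pos_i) - np.asarray(pos_j)))
    if bonded:
        return ("covalent", d, decay.step_decay("covalent"))
    if (
        el_i in chem.HBOND_ELEMENTS
        and el_j in chem.HBOND_ELEMENTS
        and not same_residue
        and 2.4 <= d <= 3.5
    ):
        return ("hbond", d, decay.step_decay("hbond", d))
    if d <= space_cutoff:
        return ("space", d, decay.step_decay("space", d))
    return None


def make_bridge_structure(design: BridgeDesign = BridgeDesign()) -> tuple[str, BridgeTruth]:
    """Generate the bridge fixture PDB text and its ground-truth record."""
    if design.bridge_res not in ("VAL", "ASP"):
        raise ValueError("bridge_res must be VAL or ASP")
    rng = np.random.default_rng(design.seed)
    u = float(rng.uniform(0.0, design.jitter)) if design.jitter > 0 else 0.0

    # --- atom inventory -----------------------------------------------------
    # residue -> list of (atom_name, element, xyz); bonds listed explicitly
    r3 = lambda x, y, z: np.round(np.array([x, y, z], dtype=float), 3)
    atoms: dict[tuple[str, int], list[tuple[str, str, np.ndarray]]] = {}
    res_names: dict[tuple[str, int], str] = {}

    if design.bridge_res == "VAL":
        bridge = {
            "N": r3(3.82, 3.5, 0.2),
            "CA": r3(4.865, 2.48, 0.2),
            "C": r3(5.93, 3.55, 0.2),
            "O": r3(5.93, 4.78, 0.2),
            "CB": r3(4.865 + u / 2, 0.95, 0.0),
            "CG1": r3(3.665, 0.0, 0.0),
            "CG2": r3(6.065 + u, 0.0, 0.0),
        }
        bridge_bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                        ("CB", "CG1"), ("CB", "CG2")]
    else:  # ASP
        bridge = {
            "N": r3(4.1 + u / 4, 3.0, 0.5),
            "CA": r3(4.1 + u / 4, 1.53, 0.0),
            "C": r3(5.0 + u / 4, 2.9, 0.9),
            "O": r3(5.0 + u / 4, 4.13, 0.9),
            "CB": r3(4.1 + u / 4, 0.0, 0.0),
            "CG": r3(5.63 + u / 2, 0.0, 0.0),
            "OD1": r3(5.0 + u / 2, 0.75, -1.0),
            "OD2": r3(5.0 + u / 2, -0.75, -1.0),
        }
        bridge_bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                        ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2"),
                        # short designed contacts that the distance criterion
                        # also classifies as bonded
                        ("CB", "OD1"), ("CB", "OD2"), ("OD1", "OD2")]

    cluster_a_center = np.array([0.0, 0.0, 0.0])
    cluster_b_center = np.array([9.73 + u, 0.0, 0.0])

    decoy1 = {"N": r3(0.95, -5.4, 0.0), "CA": r3(2.2, -4.6, 0.0), "C": r3(3.5, -3.8, 0.0)}
    decoy2 = {"N": r3(4.7, -3.25, 0.0), "CA": r3(5.45, -4.45, 0.0), "C": r3(6.8 + u, -4.15, 0.0)}

    res_names[("A", 10)] = design.bridge_res
    atoms[("A", 10)] = [
        (n, ("N" if n == "N" else "O" if n.startswith("O") else "C"), p)
        for n, p in bridge.items()
    ]
    res_names[("A", 20)] = "GLY"
    atoms[("A", 20)] = [(n, "N" if n == "N" else "C", p) for n, p in decoy1.items()]
    res_names[("A", 21)] = "GLY"
    atoms[("A", 21)] = [(n, "N" if n == "N" else "C", p) for n, p in decoy2.items()]

    # serial assignment: protein residues first, clusters last
    serial = 1
    records: list[tuple[int, str, str, str, int, np.ndarray, bool]] = []
    coords: dict[str, np.ndarray] = {}  # "seq:name" -> xyz for bookkeeping
    elements: dict[str, str] = {}
    for site in (("A", 10), ("A", 20), ("A", 21)):
        for name, el, pos in atoms[site]:
            records.append((serial, name, el, res_names[site], site[1], pos, False))
            coords[f"{site[1]}:{name}"] = pos
            elements[f"{site[1]}:{name}"] = el
            serial += 1
    cluster_a = _cluster_atoms(cluster_a_center, serial)
    serial += 8
    cluster_b = _cluster_atoms(cluster_b_center, serial)
    for seq, cluster in ((501, cluster_a), (502, cluster_b)):
        for ser, name, el, pos in cluster:
            records.append((ser, name, el, "SF4", seq, np.round(pos, 3), True))

    cluster_a_ep = [(el, np.round(p, 3)) for _, _, el, p in cluster_a]
    cluster_b_ep = [(el, np.round(p, 3)) for _, _, el, p in cluster_b]

    # --- PDB text -----------------------------------------------------------
    lines = []
    for ser, name, el, resn, seq, pos, het in records:
        rec = "HETATM" if het else "ATOM"
        name_f = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"{rec:<6s}{ser:>5d} {name_f:<4s}{resn:>4s} A{seq:>4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    # --- analytic ground truth ---------------------------------------------
    decay = design.decay
    bonded_pairs = set()
    for a, b in bridge_bonds:
        bonded_pairs.add(frozenset((f"10:{a}", f"10:{b}")))
    for seq, res in ((20, decoy1), (21, decoy2)):
        bonded_pairs.add(frozenset((f"{seq}:N", f"{seq}:CA")))
        bonded_pairs.add(frozenset((f"{seq}:CA", f"{seq}:C")))
    bonded_pairs.add(frozenset(("20:C", "21:N")))  # peptide bond

    def step(tok_i: str, tok_j: str):
        """Analytic step between two route tokens ('A', 'B', or 'seq:name')."""
        if tok_i in ("A", "B") and tok_j in ("A", "B"):
            cluster_i = cluster_a_ep if tok_i == "A" else cluster_b_ep
            cluster_j = cluster_b_ep if tok_j == "B" else cluster_a_ep
            best = None
            for ei, pi in cluster_i:
                for ej, pj in cluster_j:
                    st = _pair_step(ei, pi, ej, pj, False, False, decay)
                    if st and (best is None or st[2] > best[2]):
                        best = st
            return best
        if tok_i in ("A", "B") or tok_j in ("A", "B"):
            cl, atom_tok = (tok_i, tok_j) if tok_i in ("A", "B") else (tok_j, tok_i)
            cluster = cluster_a_ep if cl == "A" else cluster_b_ep
            el = elements[atom_tok]
            pos = coords[atom_tok]
            best = None
            for elc, pc in cluster:
                st = _pair_step(el, pos, elc, pc, False, False, decay)
                if st and (best is None or st[2] > best[2]):
                    best = st
            return best
        bonded = frozenset((tok_i, tok_j)) in bonded_pairs
        same_res = tok_i.split(":")[0] == tok_j.split(":")[0]
        return _pair_step(elements[tok_i], coords[tok_i],
                          elements[tok_j], coords[tok_j], bonded, same_res, decay)

    def route_T(route: list[str]):
        total = 1.0
        steps = []
        for ti, tj in zip(route, route[1:]):
            st = step(ti, tj)
            if st is None:
                return 0.0, []
            kind, d, eps = st
            steps.append((kind, f"{ti}-{tj}", round(d, 3), eps))
            total *= eps
        return total, steps

    def best_route(routes: list[list[str]]):
        scored = [(route_T(r), r) for r in routes]
        (T, steps), route = max(scored, key=lambda x: x[0][0])
        return T, steps, route

    decoy_route = ["A", "20:CA", "20:C", "21:N", "21:CA", "21:C", "B"]
    if design.bridge_res == "VAL":
        wt_routes = [
            ["A", "10:CG1", "10:CB", "10:CG2", "B"],
            ["A", "10:CB", "10:CG2", "B"],
            ["A", "10:CG1", "10:CB", "B"],
            ["A", "10:N", "10:CA", "10:CB", "10:CG2", "B"],
            ["A", "10:CA", "10:CB", "10:CG2", "B"],
            ["A", "10:CG1", "B"],
            ["A", "10:CG2", "B"],
            ["A", "10:CB", "B"],
            ["A", "10:CA", "10:C", "B"],
            decoy_route,
        ]
        mut_routes = {
            "A:10:VAL>ALA": [
                ["A", "10:CB", "B"],
                ["A", "10:CA", "B"],
                ["A", "10:CA", "10:C", "B"],
                ["A", "10:N", "10:CA", "10:CB", "B"],
                ["A", "10:CA", "10:CB", "B"],
                ["A", "10:N", "10:CA", "10:C", "B"],
                decoy_route,
            ],
            "A:10:VAL>GLY": [
                ["A", "10:CA", "B"],
                ["A", "10:CA", "10:C", "B"],
                ["A", "10:N", "10:CA", "10:C", "B"],
                ["A", "10:N", "10:CA", "B"],
                decoy_route,
            ],
        }
    else:
        wt_routes = [
            ["A", "10:CB", "10:CG", "B"],
            ["A", "10:CA", "10:CB", "10:CG", "B"],
            ["A", "10:CA", "B"],
            ["A", "10:CA", "10:C", "B"],
            ["A", "10:CB", "B"],
            ["A", "10:CG", "B"],
            ["A", "10:CB", "10:CG", "10:OD1", "B"],
            decoy_route,
        ]
        mut_routes = {
            "A:10:ASP>GLY": [
                ["A", "10:CA", "B"],
                ["A", "10:CA", "10:C", "B"],
                ["A", "10:N", "10:CA", "10:C", "B"],
                ["A", "10:N", "10:CA", "B"],
                decoy_route,
            ],
        }

    T_wt, wt_steps, wt_route = best_route(wt_routes)
    mutations = {}
    for mut, routes in mut_routes.items():
        T_mut, steps, route = best_route(routes)
        mutations[mut] = {
            "route": route,
            "steps": steps,
            "T": T_mut,
            "rate_ratio": (T_wt / T_mut) ** 2 if T_mut > 0 else math.inf,
        }

    min_cluster_dist = min(
        float(np.linalg.norm(pa - pb)) for _, pa in cluster_a_ep for _, pb in cluster_b_ep
    )
    truth = BridgeTruth(
        n_atoms=len(records),
        inter_cluster_min_distance=min_cluster_dist,
        wt_route=wt_route,
        wt_steps=wt_steps,
        T_wt=T_wt,
        mutations=mutations,
        cofactors={"N4": "A:501", "N5": "A:502"},
        bridge_site=("A", 10),
    )
    return pdb_text, truth


# ---------------------------------------------------------------------------
# omics fixture


@dataclass(frozen=True)
class OmicsDesign:
    """Design of a grouped log-normal abundance table with planted effects.

    ``effects`` maps feature id -> {group: fold change relative to the
    baseline}; unspecified features/groups are unchanged. ``cv`` is the
    replicate coefficient of variation on the intensity scale.
    ``dropout_midpoint`` (log2 intensity at which the dropout probability
    is 0.5) enables abundance-dependent missingness; None disables it.
    """

    n_features: int = 200
    groups: tuple[tuple[str, int], ...] = (("patient", 3), ("control", 3))
    base_log2_mean: float = 23.0
    base_log2_sd: float = 2.0
    cv: float = 0.10
    effects: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    dropout_midpoint: float | None = None
    dropout_steepness: float = 1.0
    seed: int = 0

    @staticmethod
    def pack_effects(effects: dict[str, dict[str, float]]):
        return tuple((f, tuple(sorted(gf.items()))) for f, gf in sorted(effects.items()))


def make_omics_table(design: OmicsDesign = OmicsDesign()) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate the abundance table and the planted-effect truth table."""
    rng = np.random.default_rng(design.seed)
    effects = {f: dict(gf) for f, gf in design.effects}

    named = list(effects)
    n_anon = design.n_features - len(named)
    if n_anon < 0:
        raise ValueError("n_features smaller than the number of named effect features")
    features = named + [f"F{i:04d}" for i in range(1, n_anon + 1)]

    samples = []
    group_of = {}
    for gname, nrep in design.groups:
        for r in range(1, nrep + 1):
            sid = f"{gname}_{r}"
            samples.append(sid)
            group_of[sid] = gname

    base = rng.normal(design.base_log2_mean, design.base_log2_sd, size=len(features))
    sigma_log2 = math.sqrt(math.log(1.0 + design.cv**2)) / math.log(2.0)

    log2fold = np.zeros((len(features), len(samples)))
    for i, f in enumerate(features):
        for j, s in enumerate(samples):
            fold = effects.get(f, {}).get(group_of[s], 1.0)
            log2fold[i, j] = math.log2(fold)

    noise = rng.normal(0.0, sigma_log2, size=log2fold.shape)
    log2_values = base[:, None] + log2fold + noise
    values = pd.DataFrame(2.0**log2_values, index=features, columns=samples)

    if design.dropout_midpoint is not None:
        p_drop = 1.0 / (1.0 + np.exp(
            design.dropout_steepness * (log2_values - design.dropout_midpoint)
        ))
        drop = rng.uniform(size=p_drop.shape) < p_drop
        values = values.mask(drop)

    table = AbundanceTable(
        values=values,
        groups=pd.Series(group_of),
        log2=False,
        feature_sets={},
    )
    truth_rows = []
    for f, gf in effects.items():
        for g, fold in gf.items():
            truth_rows.append({"feature": f, "group": g, "fold": fold,
                               "log2fc_true": math.log2(fold)})
    truth = pd.DataFrame(truth_rows, columns=["feature", "group", "fold", "log2fc_true"])
    return table, truth


def null_omics_design(n_features: int = 121, seed: int = 0, cv: float = 0.10) -> OmicsDesign:
    """No planted effects, no dropout: type-I error calibration."""
    return OmicsDesign(n_features=n_features, cv=cv, seed=seed)


def metabolome_design(seed: int = 0) -> OmicsDesign:
    """Targeted-metabolome-like table: 121 features, triplicates of one
    control and two patient groups, glutathione depletion planted so the
    reduced/oxidized ratio drops more than 35-fold in both patients."""
    effects = {
        "GSH": {"nd5": 1 / 12, "ndufs1": 1 / 16},
        "GSSG": {"nd5": 3.0, "ndufs1": 2.2},
    }
    return OmicsDesign(
        n_features=121,
        groups=(("control", 3), ("nd5", 3), ("ndufs1", 3)),
        cv=0.15,
        effects=OmicsDesign.pack_effects(effects),
        seed=seed,
    )


def proteome_design(seed: int = 0, n_features: int = 400,
                    dropout: bool = False) -> tuple[OmicsDesign, dict[str, tuple[str, ...]]]:
    """LFQ-proteome-like table containing every curated complex I subunit,
    with the N-module depleted 3- to 10-fold in the patient group and the
    Q/P modules left untouched. Returns the design and the module sets."""
    n_members = CI_MODULES["N"]
    named_folds = {"NDUFA7": 3.0, "NDUFV2": 4.0, "NDUFS1": 6.0, "NDUFV1": 10.0}
    others = [g for g in n_members if g not in named_folds]
    spread = np.linspace(3.0, 10.0, len(others))
    effects = {g: {"patient": 1.0 / f} for g, f in named_folds.items()}
    effects.update({g: {"patient": 1.0 / f} for g, f in zip(others, spread)})
    # ensure every CI subunit is a feature even without a planted effect
    for module in CI_MODULES.values():
        for g in module:
            effects.setdefault(g, {})
    design = OmicsDesign(
        n_features=n_features,
        effects=OmicsDesign.pack_effects(effects),
        dropout_midpoint=19.0 if dropout else None,
        seed=seed,
    )
    return design, dict(CI_MODULES)
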