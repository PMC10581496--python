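"""Reading and writing networks, structures, and run configuration.

Network spec files are JSON or YAML (by extension) with fields:

* ``units``: list of unit names
* ``alphabets``: int (shared) or per-unit list of alphabet sizes (default 2)
* ``state``: case-coded label (binary letter units, lowercase = OFF) or an
  explicit list of state indices
* exactly one of
  - ``logistic``: {"k": float, "weights": row-major matrix w[j][i], input j →
    target i, columns summing to 1}
  - ``node_tpms``: per-unit tables, each |Ω|×|A_i| (exact round-trip form)
  - ``tpm``: joint |Ω|×|Ω| row-major matrix

All state enumeration is little-endian (unit 0 varies fastest); TSV TPM files
carry a header line declaring this. Φ-structures serialize to JSON with
stable key ordering so outputs are diffable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import statespace as ss
from .network import LogisticSpec, Network, build_logistic_network, validate_tpm
from .structure import PhiStructure

__all__ = [
    "RunConfig",
    "read_network",
    "write_network",
    "read_tpm_tsv",
    "write_tpm_tsv",
    "structure_to_dict",
    "write_structure",
]


@dataclasses.dataclass
class RunConfig:
    """Tunable knobs of the analysis pipeline (defaults documented here are
    the package defaults everywhere)."""

    tolerance: float = 1e-10
    max_units: int = 8  # exhaustive subset-scan cap
    max_distinctions: int = 20  # relation-enumeration cap
    tie_break_policy: str = "phi-then-index"
    log_level: str = "INFO"
    output: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = _load(path)
        return cls(**data)

    def to_file(self, path) -> None:
        _dump(dataclasses.asdict(self), path)


def _load(path):
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump(data, path):
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def read_network(path) -> Network:
    """Load a network spec; raises ValueError naming the offending field."""
    data = _load(path)
    if not isinstance(data, dict):
        raise ValueError("network spec must be a mapping")
    try:
        units = list(data["units"])
    except KeyError:
        raise ValueError("network spec is missing 'units'") from None
    alpha = data.get("alphabets", 2)
    alphabets = [int(alpha)] * len(units) if isinstance(alpha, int) else [int(a) for a in alpha]
    if "state" not in data:
        raise ValueError("network spec is missing 'state'")
    state = data["state"]
    if isinstance(state, str):
        state = ss.parse_state_label(state, units)
    else:
        state = tuple(int(s) for s in state)
    sources = [k for k in ("logistic", "node_tpms", "tpm") if k in data]
    if len(sources) != 1:
        raise ValueError(
            f"network spec needs exactly one of 'logistic', 'node_tpms', 'tpm'; found {sources}"
        )
    if sources[0] == "logistic":
        spec = data["logistic"]
        net = build_logistic_network(
            LogisticSpec(np.asarray(spec["weights"], dtype=float), float(spec["k"])), state
        )
        return Network(units, [2] * len(units), net.node_tpms, state)
    if sources[0] == "node_tpms":
        net = Network(units, alphabets, [np.asarray(t, dtype=float) for t in data["node_tpms"]], state)
    else:
        net = Network.from_joint_tpm(units, alphabets, np.asarray(data["tpm"], dtype=float), state)
    diag = validate_tpm(net)
    if diag.bad_rows or diag.negative_entries:
        raise ValueError(f"invalid TPM in {path}: rows {diag.bad_rows} fail row-sum check")
    return net


def write_network(net: Network, path, include_joint: bool = False) -> None:
    data = {
        "units": list(net.units),
        "alphabets": list(net.alphabets),
        "state": list(net.state),
        "node_tpms": [t.tolist() for t in net.node_tpms],
    }
    if include_joint:
        data["tpm"] = net.joint_tpm().tolist()
    _dump(data, path)


_TSV_HEADER = "# joint TPM, rows = current state, cols = next state, little-endian (unit 0 fastest)"


def write_tpm_tsv(net: Network, path) -> None:
    lines = [_TSV_HEADER + f"; units={','.join(net.units)}; alphabets={','.join(map(str, net.alphabets))}"]
    for row in net.joint_tpm():
        lines.append("\t".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tpm_tsv(path, state=0) -> Network:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0]
    if not header.startswith("#"):
        raise ValueError("TSV TPM must begin with the state-order header line")
    fields = dict(
        part.strip().split("=", 1) for part in header.split(";")[1:] if "=" in part
    )
    units = fields["units"].split(",")
    alphabets = [int(a) for a in fields["alphabets"].split(",")]
    tpm = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
    if isinstance(state, int):
        state = ss.index_state(state, alphabets)
    return Network.from_joint_tpm(units, alphabets, tpm, state)


# ---------------------------------------------------------------------------
# Φ-structure serialization


def _substate_label(sub, labels) -> str:
    parts = sorted(sub)
    return ss.state_label([v for _, v in parts], [labels[p] for p, _ in parts])


def structure_to_dict(structure: PhiStructure) -> dict:
    labels = structure.labels
    sysr = structure.system_result
    dist_rows = []
    for d in sorted(structure.distinctions, key=lambda d: d.mech_mask):
        dist_rows.append(
            {
                "mechanism": _substate_label(d.mechanism, labels),
                "cause": _substate_label(d.cause, labels),
                "effect": _substate_label(d.effect, labels),
                "phi_c": d.phi_c,
                "phi_e": d.phi_e,
                "phi_d": d.phi_d,
                "order": d.order,
            }
        )
    rel_rows = []
    for r in sorted(structure.relations, key=lambda r: (r.degree, r.indices)):
        rel_rows.append(
            {
                "distinctions": [
                    _substate_label(structure.distinctions.distinctions[i].mechanism, labels)
                    for i in r.indices
                ],
                "degree": r.degree,
                "n_faces": len(r.faces),
                "joint_purview": _substate_label(r.joint_purview, labels),
                "phi_r": r.phi,
            }
        )
    return {
        "complex": {
            "members": list(structure.complex.labels),
            "state": structure.complex.state_label(),
            "phi_s": structure.complex.phi,
            "rank": structure.complex.rank,
        },
        "system": {
            "phi_s": sysr.phi,
            "phi_c": sysr.phi_c,
            "phi_e": sysr.phi_e,
            "normalized_phi": sysr.normalized_phi,
            "mip": sysr.mip.describe(labels) if sysr.mip else None,
            "ii_c": sysr.ces.ii_c,
            "ii_e": sysr.ces.ii_e,
            "cause_state": _state_label_from_index(sysr.ces.cause_state, structure),
            "effect_state": _state_label_from_index(sysr.ces.effect_state, structure),
        },
        "n_candidate_mechanisms": structure.n_candidate_mechanisms,
        "distinctions": dist_rows,
        "relations": rel_rows,
        "ledger": {
            "sum_phi_d": structure.sum_phi_d,
            "sum_phi_r": structure.sum_phi_r,
            "n_distinctions": len(structure.distinctions),
            "n_relations": len(structure.relations),
        },
        "big_phi": structure.big_phi,
        "units": "ibits",
    }


def _state_label_from_index(idx, structure):
    if idx is None:
        return None
    alphabets = (
        structure.system.alphabets if structure.system is not None else [2] * len(structure.labels)
    )
    return ss.state_label(ss.index_state(idx, alphabets), structure.labels)


def write_structure(structure: PhiStructure, path) -> None:
    """JSON with stable key order; Φ appears both as components and total."""
    Path(path).write_text(json.dumps(structure_to_dict(structure), indent=1) + "\n")
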