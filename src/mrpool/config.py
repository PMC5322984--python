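"""Structured-text serialization of tissue models, timelines, and
experiment configurations.

The native schema is YAML; a flat ``key=value`` dialect and a minimal
XML import shim map onto the same dictionaries.  Tissue model schema::

    name: cartilage
    proton_density: 1.0
    pools:
      - {name: water, kind: free, fraction: 0.89, t1: 1.8, t2: 0.04}
      - {name: hydroxyl, kind: free, fraction: 0.003, t1: 1.0, t2: 0.01,
         spectrum: [[1.0, 1.0]]}
      - {name: collagen, kind: bound, fraction: 0.107, t1: 1.0, t2: 8.5e-6,
         lineshape: super_lorentzian}
    exchange:                  # row -> column rates, s^-1
      - [0, 2.1, 4.5]
      - [700, 0, 0]
      - [40, 0, 0]
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET

import numpy as np
import yaml

from .sequence import ExternalEvent, SequenceSegment, Timeline
from .tissue import ExchangeMatrix, PoolSpec, TissueModel

__all__ = [
    "tissue_to_dict", "tissue_from_dict",
    "save_tissue", "load_tissue",
    "timeline_to_dict", "timeline_from_dict",
    "config_hash",
]


def tissue_to_dict(model: TissueModel) -> dict:
    pools = []
    for p in model.pools:
        d = {"name": p.name, "kind": p.kind, "fraction": float(p.fraction),
             "t1": float(p.t1), "t2": float(p.t2)}
        if p.kind == "free":
            d["spectrum"] = [[float(a), float(b)] for a, b in p.spectrum]
        else:
            d["lineshape"] = p.lineshape
        pools.append(d)
    return {"name": model.name, "proton_density": float(model.proton_density),
            "pools": pools,
            "exchange": [[float(v) for v in row]
                         for row in model.exchange.rates]}


def tissue_from_dict(d: dict) -> TissueModel:
    pools = []
    for p in d["pools"]:
        pools.append(PoolSpec(
            name=p["name"], kind=p["kind"], fraction=float(p["fraction"]),
            t1=float(p["t1"]), t2=float(p["t2"]),
            spectrum=tuple(map(tuple, p.get("spectrum", [[0.0, 1.0]]))),
            lineshape=p.get("lineshape")))
    return TissueModel(tuple(pools), ExchangeMatrix(np.array(d["exchange"])),
                       proton_density=float(d.get("proton_density", 1.0)),
                       name=d.get("name", "tissue"))


def save_tissue(model: TissueModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(tissue_to_dict(model), fh, sort_keys=False)


def _parse_flat(text: str) -> dict:
    """Flat key=value dialect: dotted paths, e.g.
    ``pools.0.name=water`` and ``exchange.1.0=700``."""
    root: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        parts = key.strip().split(".")
        node = root
        for a, b in zip(parts[:-1], parts[1:]):
            nxt = [] if b.isdigit() else {}
            if a.isdigit():
                a = int(a)
                while len(node) <= a:
                    node.append(None)
                if node[a] is None:
                    node[a] = nxt
                node = node[a]
            else:
                node = node.setdefault(a, nxt)
        leaf = parts[-1]
        try:
            parsed = yaml.safe_load(val.strip())
        except yaml.YAMLError:
            parsed = val.strip()
        if leaf.isdigit():
            leaf = int(leaf)
            while len(node) <= leaf:
                node.append(None)
            node[leaf] = parsed
        else:
            node[leaf] = parsed
    return root


def _parse_xml(text: str) -> dict:
    """XML import shim: element tree converted to the same nested
    dictionaries (repeated tags become lists; text parsed as YAML
    scalars)."""
    def conv(el):
        children = list(el)
        if not children:
            return yaml.safe_load(el.text) if el.text and el.text.strip() \
                else None
        names = [c.tag for c in children]
        if len(set(names)) == 1 and len(names) > 1:
            return [conv(c) for c in children]
        return {c.tag: conv(c) for c in children}
    return conv(ET.fromstring(text))


def load_tissue(path) -> TissueModel:
    """Read a tissue model from YAML, flat key=value, or XML text."""
    text = open(path).read()
    if text.lstrip().startswith("<"):
        return tissue_from_dict(_parse_xml(text))
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.strip().startswith("#")]
    if lines and "=" in lines[0] and ":" not in lines[0].partition("=")[0]:
        return tissue_from_dict(_parse_flat(text))
    return tissue_from_dict(yaml.safe_load(text))


def timeline_to_dict(tl: Timeline) -> dict:
    return {
        "segments": [
            {"start": s.start, "duration": s.duration,
             "rf": list(s.rf) if s.rf else None,
             "gradient": list(s.gradient), "adc": list(s.adc)}
            for s in tl.segments],
        "events": [{"time": e.time, "action": e.action,
                    "payload": dict(e.payload)} for e in tl.events],
        "metadata": _jsonable(tl.metadata),
    }


def timeline_from_dict(d: dict) -> Timeline:
    segs = [SequenceSegment(s["start"], s["duration"],
                            tuple(s["rf"]) if s.get("rf") else None,
                            tuple(s.get("gradient", (0, 0, 0))),
                            tuple(s.get("adc", ())))
            for s in d.get("segments", [])]
    evs = [ExternalEvent(e["time"], e["action"], dict(e.get("payload", {})))
           for e in d.get("events", [])]
    return Timeline(segs, evs, dict(d.get("metadata", {})))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: dict) -> str:
    """Stable sha256 of a configuration dictionary (provenance)."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
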