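"""JSON model documents.

Schema (top level): ``{"family": "standard"|"csi"|"dtree", "pi": [...],
...}``.  Standard models carry ``"components"`` (a list of product
components, each a list of per-feature distribution dicts); CSI models carry
``"blocks"`` and ``"dists"`` per feature; dependence-tree models carry per
component a parent map, root and conditional dicts.  Distribution dicts are
the ``to_dict`` forms of :mod:`hetmix.distributions` / :mod:`hetmix.trees`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .csi import CSIMixtureModel, CSIStructure
from .distributions import (DiscreteDistribution, ExponentialDistribution,
                            GaussianDistribution, ProductComponent)
from .mixture import MixtureModel
from .trees import (ConditionalDiscrete, ConditionalGaussian, DTreeComponent,
                    DTreeMixtureModel, TreeTopology)

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def _dist_from_dict(d: dict):
    t = d["type"]
    if t == "gaussian":
        return GaussianDistribution(d["mean"], d["stdev"])
    if t == "discrete":
        return DiscreteDistribution(d["alphabet"], d["probs"],
                                    pseudocount=d.get("pseudocount", 0.1))
    if t == "exponential":
        return ExponentialDistribution(d["rate"])
    if t == "cond_gaussian":
        return ConditionalGaussian(d["intercept"], d["slope"],
                                   d["noise_stdev"])
    if t == "cond_discrete":
        return ConditionalDiscrete(d["parent_alphabet"], d["child_alphabet"],
                                   d["table"],
                                   pseudocount=d.get("pseudocount", 0.1))
    raise ValueError(f"unknown distribution type {t!r}")


def model_to_dict(model: MixtureModel) -> dict:
    if isinstance(model, CSIMixtureModel):
        s = model.structure
        return {"family": "csi", "pi": model.pi.tolist(),
                "blocks": [[list(b) for b in feat] for feat in s.blocks],
                "dists": [[d.to_dict() for d in feat] for feat in s.dists]}
    if isinstance(model.components[0], DTreeComponent):
        return {"family": "dtree", "pi": model.pi.tolist(),
                "components": [c.to_dict() for c in model.components]}
    return {"family": "standard", "pi": model.pi.tolist(),
            "components": [c.to_dict() for c in model.components]}


def model_from_dict(doc: dict) -> MixtureModel:
    family = doc.get("family")
    pi = np.asarray(doc["pi"], dtype=float)
    if family == "standard":
        comps = [ProductComponent([_dist_from_dict(f) for f in c["features"]])
                 for c in doc["components"]]
        return MixtureModel(pi, comps)
    if family == "csi":
        blocks = [[tuple(b) for b in feat] for feat in doc["blocks"]]
        dists = [[_dist_from_dict(d) for d in feat] for feat in doc["dists"]]
        return CSIMixtureModel(pi, CSIStructure(blocks, dists))
    if family == "dtree":
        comps = []
        for c in doc["components"]:
            topo = TreeTopology(c["parent"], c["root"])
            edge = {int(j): _dist_from_dict(d)
                    for j, d in c["edge_dists"].items()}
            comps.append(DTreeComponent(topo, _dist_from_dict(c["root_dist"]),
                                        edge))
        return DTreeMixtureModel(pi, comps)
    raise ValueError(f"unknown or missing model family {family!r}")


def save_model(model: MixtureModel, path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n")


def load_model(path) -> MixtureModel:
    return model_from_dict(json.loads(Path(path).read_text()))
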