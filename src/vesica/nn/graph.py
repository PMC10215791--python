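"""Named-node DAG container for the layer library.

A :class:`Network` is an ordered list of nodes, each owning a layer, the
names of its input nodes ("input" denotes the network input) and a *group*
tag (``backbone`` / ``seg`` / ``clf``) used for staged freezing and for
merging separately trained paths.  The node order must be topological,
which the builders in :mod:`vesica.net_arch` guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Layer


@dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str]
    group: str = "backbone"


class Network:
    def __init__(self, outputs: dict[str, str]):
        self.nodes: list[Node] = []
        self.by_name: dict[str, Node] = {}
        self.outputs = dict(outputs)  # head name -> node name

    def add(self, name, layer, inputs, group="backbone") -> str:
        if name in self.by_name:
            raise ValueError(f"duplicate node name {name!r}")
        node = Node(name, layer, list(inputs), group)
        self.nodes.append(node)
        self.by_name[name] = node
        return name

    # ------------------------------------------------------------------ state
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for node in self.nodes:
            for pname, val in node.layer.params.items():
                out[f"{node.name}/{pname}"] = val.copy()
            if hasattr(node.layer, "running_mean"):
                out[f"{node.name}/running_mean"] = node.layer.running_mean.copy()
                out[f"{node.name}/running_var"] = node.layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, val in state.items():
            nname, pname = key.rsplit("/", 1)
            node = self.by_name.get(nname)
            if node is None:
                raise KeyError(f"no node named {nname!r} in this graph")
            if pname in ("running_mean", "running_var"):
                setattr(node.layer, pname, val.copy())
            else:
                node.layer.params[pname][...] = val

    def set_qat(self, enabled: bool) -> None:
        for node in self.nodes:
            node.layer.qat = enabled

    # ---------------------------------------------------------------- running
    def forward(self, x: np.ndarray, training: bool = False) -> dict[str, np.ndarray]:
        acts: dict[str, np.ndarray] = {"input": x}
        for node in self.nodes:
            ins = [acts[i] for i in node.inputs]
            acts[node.name] = node.layer.forward(*ins, training=training)
        self._acts = acts
        return {head: acts[nname] for head, nname in self.outputs.items()}

    def activations(self) -> dict[str, np.ndarray]:
        return self._acts

    def _needs_grad(self, trainable_groups: set[str]) -> set[str]:
        """Nodes whose backward must run: those with a trainable ancestor."""
        needed: set[str] = set()
        for node in self.nodes:  # topological order
            has_param = bool(node.layer.params) and node.group in trainable_groups
            if has_param or any(i in needed for i in node.inputs):
                needed.add(node.name)
        return needed

    def backward(self, head_grads: dict[str, np.ndarray], trainable_groups=None) -> None:
        groups = set(trainable_groups) if trainable_groups else {n.group for n in self.nodes}
        needed = self._needs_grad(groups)
        pending: dict[str, np.ndarray] = {}
        for head, g in head_grads.items():
            nname = self.outputs[head]
            pending[nname] = pending.get(nname, 0) + g
        for node in reversed(self.nodes):
            if node.name not in pending or node.name not in needed:
                continue
            gy = pending.pop(node.name)
            gx = node.layer.backward(gy)
            if not isinstance(gx, tuple):
                gx = (gx,)
            for iname, g in zip(node.inputs, gx):
                if iname == "input" or iname not in needed:
                    continue
                if iname in pending:
                    pending[iname] = pending[iname] + g
                else:
                    pending[iname] = g

    # ------------------------------------------------------------- accounting
    def parameters(self, groups=None):
        for node in self.nodes:
            if groups is not None and node.group not in groups:
                continue
            for pname, val in node.layer.params.items():
                yield f"{node.name}/{pname}", node.layer, pname, val

    def param_count(self, groups=None) -> int:
        return int(
            sum(val.size for _, _, _, val in self.parameters(groups))
        )

    def has_activation_multiply(self) -> bool:
        """Quantization-friendliness audit: any activation x activation product?"""
        return any(n.layer.kind == "multiply" and len(n.inputs) >= 2 for n in self.nodes)
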