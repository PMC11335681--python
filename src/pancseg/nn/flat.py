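"""Flat-vector view of a nested parameter tree.

Differentiating with respect to one 1D array (and rebuilding the nested
dict from traced slices inside the objective) keeps the autograd tape
small and lets slice gradients accumulate sparsely into a single buffer,
which is far cheaper than tracing a nested dict container.
"""

from __future__ import annotations

import numpy as np

Spec = list[tuple[tuple, int, tuple]]  # (path, offset, shape)


def flatten_tree(tree) -> tuple[np.ndarray, Spec]:
    leaves: list[np.ndarray] = []
    spec: Spec = []
    offset = 0

    def walk(t, path):
        nonlocal offset
        if isinstance(t, dict):
            for k, v in t.items():
                walk(v, path + (k,))
        elif isinstance(t, (list, tuple)):
            for i, v in enumerate(t):
                walk(v, path + (i,))
        else:
            arr = np.asarray(t, dtype=float)
            leaves.append(arr.ravel())
            spec.append((path, offset, arr.shape))
            offset += arr.size

    walk(tree, ())
    theta = np.concatenate(leaves) if leaves else np.zeros(0)
    return theta, spec


def unflatten_tree(theta, spec: Spec):
    """Rebuild the nested structure; containers are plain dicts/lists, the
    leaves are (possibly traced) views into ``theta``."""
    root: dict | list | None = None

    def ensure(container, key, template):
        if isinstance(container, list):
            while len(container) <= key:
                container.append(None)
            if container[key] is None:
                container[key] = template
            return container[key]
        if key not in container:
            container[key] = template
        return container[key]

    for path, offset, shape in spec:
        size = int(np.prod(shape, dtype=int))
        leaf = theta[offset:offset + size]
        if shape != (size,):
            leaf = leaf.reshape(shape) if shape else leaf[0]
        if root is None:
            root = [] if isinstance(path[0], int) else {}
        node = root
        for i, key in enumerate(path[:-1]):
            template = [] if isinstance(path[i + 1], int) else {}
            node = ensure(node, key, template)
        last = path[-1]
        if isinstance(node, list):
            while len(node) <= last:
                node.append(None)
            node[last] = leaf
        else:
            node[last] = leaf
    return root
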