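"""A small named-node taxonomy with parent links and LCA queries.

The packaged default tree covers the taxa whose milk proteins are
recoverable from steppe dental calculus: the ruminant infraorder Pecora
(bovids — cattle, buffalo, bison, sheep, goat — and cervids) plus the
equids, under a single mammalian root.  Trees are editable via a TSV of
``child<TAB>parent<TAB>rank`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Taxonomy", "default_taxonomy", "DEFAULT_EDGES"]

# child, parent, rank-of-child
DEFAULT_EDGES: tuple[tuple[str, str, str], ...] = (
    ("Pecora", "Mammalia", "infraorder"),
    ("Bovidae", "Pecora", "family"),
    ("Cervidae", "Pecora", "family"),
    ("Bovinae", "Bovidae", "subfamily"),
    ("Caprinae", "Bovidae", "subfamily"),
    ("Bos", "Bovinae", "genus"),
    ("Bubalus", "Bovinae", "genus"),
    ("Bison", "Bovinae", "genus"),
    ("Ovis", "Caprinae", "genus"),
    ("Capra", "Caprinae", "genus"),
    ("Cervus", "Cervidae", "genus"),
    ("Equidae", "Mammalia", "family"),
    ("Equus", "Equidae", "genus"),
)


@dataclass(frozen=True)
class _Node:
    name: str
    parent: str | None
    rank: str


class Taxonomy:
    """Rooted tree of named, ranked nodes supporting ancestor/LCA queries."""

    def __init__(self, edges: tuple[tuple[str, str, str], ...] | list):
        self._nodes: dict[str, _Node] = {}
        children_of: dict[str, list[str]] = {}
        parents = set()
        for child, parent, rank in edges:
            if child in self._nodes:
                raise ValueError(f"duplicate taxon name: {child!r}")
            self._nodes[child] = _Node(child, parent, rank)
            children_of.setdefault(parent, []).append(child)
            parents.add(parent)
        roots = parents - set(self._nodes)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        self.root = roots.pop()
        self._nodes[self.root] = _Node(self.root, None, "root")
        # cycle check via root-path walk with a step bound
        for name in self._nodes:
            self.path_to_root(name)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    @property
    def names(self) -> list[str]:
        return sorted(self._nodes)

    def rank(self, name: str) -> str:
        return self._nodes[name].rank

    def path_to_root(self, name: str) -> list[str]:
        """Node names from ``name`` up to and including the root."""
        if name not in self._nodes:
            raise KeyError(f"unknown taxon: {name!r}")
        path, seen = [], set()
        node: str | None = name
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle in taxonomy at {node!r}")
            seen.add(node)
            path.append(node)
            node = self._nodes[node].parent
        return path

    def depth(self, name: str) -> int:
        return len(self.path_to_root(name)) - 1

    def is_ancestor_or_self(self, ancestor: str, name: str) -> bool:
        return ancestor in self.path_to_root(name)

    def lca(self, names) -> str:
        """Lowest common ancestor of one or more node names.

        Walks the deeper node up until both paths meet; a singleton input
        returns the node itself.
        """
        names = list(names)
        if not names:
            raise ValueError("lca of an empty taxon set is undefined")
        current = names[0]
        for other in names[1:]:
            a, b = current, other
            while self.depth(a) > self.depth(b):
                a = self._nodes[a].parent  # type: ignore[assignment]
            while self.depth(b) > self.depth(a):
                b = self._nodes[b].parent  # type: ignore[assignment]
            while a != b:
                a = self._nodes[a].parent  # type: ignore[assignment]
                b = self._nodes[b].parent  # type: ignore[assignment]
            current = a
        return current

    # ---- serialization -------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        edges = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: expected child<TAB>parent<TAB>rank")
                edges.append(tuple(parts))
        return cls(edges)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in sorted(self._nodes):
                node = self._nodes[name]
                if node.parent is not None:
                    fh.write(f"{node.name}\t{node.parent}\t{node.rank}\n")


def default_taxonomy() -> Taxonomy:
    return Taxonomy(DEFAULT_EDGES)
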