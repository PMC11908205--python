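"""Pedigrees and pedigree kinship.

A pedigree stores, per diploid individual, the indices of its two parents
(-1 = unknown, treated as founder) and a generation index (parents have a
strictly smaller generation than their children).  Kinship theta(i, j) is
the probability that one genome copy drawn at random from i and one from j
are identical by descent within the pedigree; it is computed by the
standard recursion (the "tabular method"):

    theta(i, j) = (theta(father(i), j) + theta(mother(i), j)) / 2
                                         for i not an ancestor of j,
    theta(i, i) = (1 + theta(father(i), mother(i))) / 2,
    founders:  theta(i, i) = 1/2,  theta(i, j) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "kinship_matrix",
    "make_pedigree",
    "relationship_panel_pedigree",
    "load_pedigree",
    "save_pedigree",
]

NULL = -1


@dataclass
class Pedigree:
    """Parent pointers per diploid individual.

    ``father``/``mother`` hold parent indices (-1 = founder side),
    ``generation`` increases from founders to probands, ``is_proband``
    flags the focal individuals.
    """

    father: np.ndarray
    mother: np.ndarray
    generation: np.ndarray
    is_proband: np.ndarray

    def __post_init__(self):
        self.father = np.asarray(self.father, dtype=np.int64)
        self.mother = np.asarray(self.mother, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.is_proband = np.asarray(self.is_proband, dtype=bool)
        n = len(self.father)
        for name, par in (("father", self.father), ("mother", self.mother)):
            if np.any((par != NULL) & ((par < 0) | (par >= n))):
                raise ValueError(f"{name} index out of range")
            ok = (par == NULL) | (self.generation[par] < self.generation)
            if not np.all(ok):
                bad = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"individual {bad}: {name} must belong to an earlier generation"
                )

    @property
    def num_individuals(self) -> int:
        return len(self.father)

    @property
    def probands(self) -> np.ndarray:
        return np.flatnonzero(self.is_proband)

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.father == NULL) & (self.mother == NULL))

    def topological_order(self) -> np.ndarray:
        """Individuals sorted so parents precede children."""
        return np.argsort(self.generation, kind="stable")


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense kinship matrix theta over all individuals.

    Unknown parents are treated as unique unrelated founders.
    """
    n = ped.num_individuals
    theta = np.zeros((n, n))
    order = ped.topological_order()
    done: list[int] = []
    done_mask = np.zeros(n, dtype=bool)
    for i in order:
        f, m = ped.father[i], ped.mother[i]
        row = np.zeros(n)
        if len(done):
            d = np.asarray(done)
            contrib = np.zeros(len(d))
            if f != NULL:
                contrib += theta[f, d]
            if m != NULL:
                contrib += theta[m, d]
            row[d] = contrib / 2.0
        theta[i, :] = row
        theta[:, i] = row
        self_k = 0.5
        if f != NULL and m != NULL:
            self_k = 0.5 * (1.0 + theta[f, m])
        theta[i, i] = self_k
        done.append(int(i))
        done_mask[i] = True
    return theta


# ---------------------------------------------------------------------------
# synthetic pedigree builders
# ---------------------------------------------------------------------------

def make_pedigree(
    generations: int,
    n_founder_couples: int = 8,
    sibship_size: int = 2,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Random-mating synthetic pedigree with monogamous couples.

    Each generation's couples produce ``sibship_size`` children; children
    are paired at random with non-siblings (individuals left without a
    compatible partner marry a fresh founder).  The final generation is
    flagged as probands.  With sibship sizes >= 2 this produces
    identifiable full-sibling and cousin pairs.
    """
    if generations < 2:
        raise ValueError("a pedigree needs at least 2 generations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    father: list[int] = []
    mother: list[int] = []
    gen: list[int] = []

    def add(f: int, m: int, g: int) -> int:
        father.append(f)
        mother.append(m)
        gen.append(g)
        return len(father) - 1

    couples = [(add(NULL, NULL, 0), add(NULL, NULL, 0)) for _ in range(n_founder_couples)]
    for g in range(1, generations):
        children = []
        sib_of = {}
        for ci, (f, m) in enumerate(couples):
            for _ in range(sibship_size):
                c = add(f, m, g)
                children.append(c)
                sib_of[c] = ci
        rng.shuffle(children)
        couples = []
        pool = list(children)
        while pool:
            a = pool.pop()
            partner = None
            for idx, b in enumerate(pool):
                if sib_of[b] != sib_of[a]:
                    partner = pool.pop(idx)
                    break
            if partner is None:
                partner = add(NULL, NULL, g)  # marries into the pedigree
            couples.append((a, partner))
    is_proband = np.asarray(gen) == generations - 1
    return Pedigree(np.asarray(father), np.asarray(mother), np.asarray(gen), is_proband)


def relationship_panel_pedigree(
    pairs_per_type: int = 1, n_unrelated: int = 2
) -> tuple[Pedigree, dict[str, list[tuple[int, int]]]]:
    """Deterministic pedigree containing labelled proband pairs of known
    kinship: full siblings (1/4), first (1/16), second (1/64) and third
    (1/256) cousins, plus unrelated probands.

    A k-th cousin pair descends from one ancestral couple k+1 generations
    above the probands, through two lines that marry unrelated founders at
    every step.  All probands sit in the same (final) generation so branch
    relatedness is comparable across pair types.

    Returns the pedigree and a mapping from relationship label to the list
    of proband index pairs.
    """
    father: list[int] = []
    mother: list[int] = []
    gen: list[int] = []

    def add(f: int, m: int, g: int) -> int:
        father.append(f)
        mother.append(m)
        gen.append(g)
        return len(father) - 1

    depth = 4  # generations above probands needed for third cousins
    final = depth
    pairs: dict[str, list[tuple[int, int]]] = {
        "sibling": [],
        "first_cousin": [],
        "second_cousin": [],
        "third_cousin": [],
        "unrelated": [],
    }
    degree_of = {"sibling": 0, "first_cousin": 1, "second_cousin": 2, "third_cousin": 3}
    for label, k in degree_of.items():
        for _ in range(pairs_per_type):
            top_gen = final - 1 - k
            f0 = add(NULL, NULL, top_gen)
            m0 = add(NULL, NULL, top_gen)
            lines = [add(f0, m0, top_gen + 1), add(f0, m0, top_gen + 1)]
            for g in range(top_gen + 2, final + 1):
                nxt = []
                for x in lines:
                    spouse = add(NULL, NULL, g - 1)
                    nxt.append(add(x, spouse, g))
                lines = nxt
            pairs[label].append((lines[0], lines[1]))
    singles = []
    for _ in range(n_unrelated):
        f0 = add(NULL, NULL, final - 1)
        m0 = add(NULL, NULL, final - 1)
        singles.append(add(f0, m0, final))
    for a in range(len(singles)):
        for b in range(a + 1, len(singles)):
            pairs["unrelated"].append((singles[a], singles[b]))
    gen_arr = np.asarray(gen)
    is_proband = gen_arr == final
    ped = Pedigree(np.asarray(father), np.asarray(mother), gen_arr, is_proband)
    return ped, pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        {
            "id": np.arange(ped.num_individuals),
            "father": ped.father,
            "mother": ped.mother,
            "generation": ped.generation,
            "is_proband": ped.is_proband.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def load_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("id").reset_index(drop=True)
    if not np.array_equal(df["id"].to_numpy(), np.arange(len(df))):
        raise ValueError("pedigree ids must be exactly 0..n-1")
    return Pedigree(
        df["father"].to_numpy(dtype=np.int64),
        df["mother"].to_numpy(dtype=np.int64),
        df["generation"].to_numpy(dtype=np.int64),
        df["is_proband"].to_numpy(dtype=bool),
    )
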