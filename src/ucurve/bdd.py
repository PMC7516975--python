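"""A minimal reduced ordered binary decision diagram (ROBDD).

Just enough BDD algebra to hold a family of fixed-width bit words and remove
lattice intervals from it: hash-consed nodes, conjunction, direct
construction of a cube and of a negated cube, membership, exact model
counting and uniform random model sampling.  Variables are word bit
positions 0..n-1, tested in increasing order.
"""

from __future__ import annotations

FALSE = 0
TRUE = 1


class BDD:
    """Node store for ROBDDs over ``nvars`` boolean variables.

    Functions are node ids (ints); 0 and 1 are the terminals.  Nodes are
    hash-consed, so equal functions share an id and emptiness is ``f == 0``.
    """

    def __init__(self, nvars: int):
        if nvars < 0:
            raise ValueError("number of variables must be non-negative")
        self.nvars = nvars
        self._var = {FALSE: nvars, TRUE: nvars}   # terminal "variable" sentinel
        self._lo = {}
        self._hi = {}
        self._unique: dict = {}
        self._and_memo: dict = {}
        self._count_memo: dict = {FALSE: 0, TRUE: 1}
        self._next_id = 2

    # -- construction -------------------------------------------------------
    def mk(self, var: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (var, lo, hi)
        node = self._unique.get(key)
        if node is None:
            node = self._next_id
            self._next_id += 1
            self._unique[key] = node
            self._var[node] = var
            self._lo[node] = lo
            self._hi[node] = hi
        return node

    def cube(self, literals) -> int:
        """Conjunction of literals [(var, value), ...]; vars distinct."""
        node = TRUE
        for var, value in sorted(literals, reverse=True):
            node = self.mk(var, FALSE, node) if value else self.mk(var, node, FALSE)
        return node

    def neg_cube(self, literals) -> int:
        """Negation of a cube, built directly (no general NOT needed)."""
        node = FALSE
        for var, value in sorted(literals, reverse=True):
            node = self.mk(var, TRUE, node) if value else self.mk(var, node, TRUE)
        return node

    # -- conjunction ---------------------------------------------------------
    def conj(self, f: int, g: int) -> int:
        if f == FALSE or g == FALSE:
            return FALSE
        if f == TRUE:
            return g
        if g == TRUE or f == g:
            return f
        key = (f, g) if f <= g else (g, f)
        memo = self._and_memo.get(key)
        if memo is not None:
            return memo
        vf, vg = self._var[f], self._var[g]
        v = min(vf, vg)
        flo, fhi = (self._lo[f], self._hi[f]) if vf == v else (f, f)
        glo, ghi = (self._lo[g], self._hi[g]) if vg == v else (g, g)
        result = self.mk(v, self.conj(flo, glo), self.conj(fhi, ghi))
        self._and_memo[key] = result
        return result

    # -- queries -------------------------------------------------------------
    def member(self, f: int, word: int) -> bool:
        while f > TRUE:
            v = self._var[f]
            f = self._hi[f] if word >> v & 1 else self._lo[f]
        return f == TRUE

    def _raw_count(self, f: int) -> int:
        """Model count over variables var(f)..nvars-1 (terminals: 0 or 1)."""
        memo = self._count_memo.get(f)
        if memo is not None:
            return memo
        v = self._var[f]
        lo, hi = self._lo[f], self._hi[f]
        count = (self._raw_count(lo) << (self._var[lo] - v - 1)) + \
                (self._raw_count(hi) << (self._var[hi] - v - 1))
        self._count_memo[f] = count
        return count

    def count(self, f: int) -> int:
        """Number of satisfying words of width ``nvars``."""
        return self._raw_count(f) << self._var[f] if f > TRUE else (
            (1 << self.nvars) if f == TRUE else 0)

    def sample(self, f: int, rng) -> int:
        """Uniform random satisfying word; ``f`` must be satisfiable."""
        if f == FALSE:
            raise ValueError("cannot sample from the empty family")
        word = 0
        var = 0
        while True:
            top = self._var[f]
            # variables skipped before the node (or before the terminal) are free
            for v in range(var, top):
                if int(rng.integers(2)):
                    word |= 1 << v
            if f <= TRUE:
                return word
            lo, hi = self._lo[f], self._hi[f]
            w_lo = self._raw_count(lo) << (self._var[lo] - top - 1) if lo != FALSE else 0
            w_hi = self._raw_count(hi) << (self._var[hi] - top - 1) if hi != FALSE else 0
            if int(rng.integers(w_lo + w_hi)) < w_hi:
                word |= 1 << top
                f = hi
            else:
                f = lo
            var = top + 1

    def iter_words(self, f: int):
        """Yield all satisfying words (exhaustive; small families only)."""
        n = self.nvars

        def rec(node: int, var: int, prefix: int):
            if node == FALSE:
                return
            top = self._var[node]
            free = []
            for v in range(var, top):
                free.append(v)

            def expand(base: int, idx: int):
                if idx == len(free):
                    if node == TRUE:
                        yield base
                    else:
                        yield from rec(self._lo[node], top + 1, base)
                        yield from rec(self._hi[node], top + 1, base | (1 << top))
                else:
                    yield from expand(base, idx + 1)
                    yield from expand(base | (1 << free[idx]), idx + 1)

            yield from expand(prefix, 0)

        yield from rec(f, 0, 0)
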