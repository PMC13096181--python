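"""Porter suffix-stripping stemmer.

Implements the classic 1980 algorithm (steps 1a-5b) for lowercase ASCII
tokens, e.g. ``"pollinating" -> "pollin"``, ``"bees" -> "bee"``. Alias
matching in :mod:`beebias.corpus` depends on this being deterministic and
applied identically to queries and documents, so the algorithm lives here
as a small, dependency-free module.

Only :func:`stem` is public. Tokens of length <= 2 are returned unchanged,
as in the original description.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences: [C](VC)^m[V]."""
    m = 0
    i = 0
    n = len(stem)
    while i < n and _cons(stem, i):
        i += 1
    while True:
        while i < n and not _cons(stem, i):
            i += 1
        if i >= n:
            return m
        while i < n and _cons(stem, i):
            i += 1
        m += 1
        if i >= n:
            return m


def _has_vowel(stem: str) -> bool:
    return any(not _cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(w: str) -> bool:
    return len(w) >= 2 and w[-1] == w[-2] and _cons(w, len(w) - 1)


def _cvc(w: str) -> bool:
    if len(w) < 3:
        return False
    return (
        _cons(w, len(w) - 3)
        and not _cons(w, len(w) - 2)
        and _cons(w, len(w) - 1)
        and w[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    stripped = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        stripped = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        stripped = True
    if stripped:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_cons(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


# Ordered so that any suffix is listed before every proper suffix of it
# that also appears ("ization" before "ation", "ational" before "tional",
# "ement" before "ment" before "ent"). Matching stops at the first listed
# suffix the word ends with, whether or not the measure condition passes.
_STEP2 = (
    ("ization", "ize"),
    ("ational", "ate"),
    ("iveness", "ive"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("tional", "tion"),
    ("biliti", "ble"),
    ("ousli", "ous"),
    ("entli", "ent"),
    ("ation", "ate"),
    ("alism", "al"),
    ("aliti", "al"),
    ("iviti", "ive"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("izer", "ize"),
    ("abli", "able"),
    ("alli", "al"),
    ("ator", "ate"),
    ("eli", "e"),
)

_STEP3 = (
    ("icate", "ic"),
    ("ative", ""),
    ("alize", "al"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ness", ""),
    ("ful", ""),
)

_STEP4 = (
    "ement",
    "ance",
    "ence",
    "able",
    "ible",
    "ment",
    "ent",
    "ant",
    "ion",
    "ism",
    "ate",
    "iti",
    "ous",
    "ive",
    "ize",
    "ou",
    "er",
    "ic",
    "al",
)


def _apply_rules(w: str, rules, min_measure: int) -> str:
    for suffix, repl in rules:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > min_measure:
                return stem + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    return w
                return stem
            return w
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and w.endswith("ll"):
        return w[:-1]
    return w


def stem(token: str) -> str:
    """Stem a single lowercase token with the Porter algorithm."""
    w = token
    if len(w) <= 2:
        return w
    w = _step1a(w)
    w = _step1b(w)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w
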