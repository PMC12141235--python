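"""Canonical name dictionaries and harmonization.

Surveillance disclosures spell vegetable categories, pesticides and provinces
inconsistently across bureaus. Harmonization maps every raw spelling to a
single canonical form via an editable synonym dictionary; names absent from
the dictionary come back as *unmapped* rather than passing through silently,
so the cleaning step can count and drop them.

The packaged dictionaries are deliberately small working sets (the categories
and compounds that dominate national surveillance), not a full national
classification standard; callers can extend them via ``build_dictionary``.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .geodata import PROVINCIAL_CAPITALS

#: sentinel returned for names not present in a dictionary
UNMAPPED = None

# Canonical vegetable categories (working set from national surveillance).
VEGETABLES: tuple[str, ...] = (
    "pepper", "chinese cabbage", "tomato", "eggplant", "celery", "potato",
    "cowpea", "leek", "ginger", "bean sprout", "cucumber", "radish",
    "leaf-used lettuce", "spinach", "mushroom", "head cabbage", "yam",
    "kidney bean", "lotus root", "shallot", "balsam pear", "onion",
    "sweet potato", "broccoli", "garlic sprout", "lettuce", "cucurbita pepo",
    "cauliflower", "day-lily flower", "pumpkin", "wax gourd", "water spinach",
    "chrysanthemum", "luffa", "garlic", "mustard", "colocasia esculenta",
    "amaranth", "bottle gourd", "snow peas", "coriander", "okra",
)

VEGETABLE_ALIASES: dict[str, str] = {
    "chili": "pepper",
    "chilli": "pepper",
    "hot pepper": "pepper",
    "capsicum": "pepper",
    "napa cabbage": "chinese cabbage",
    "pak choi": "chinese cabbage",
    "aubergine": "eggplant",
    "chinese chive": "leek",
    "chinese leek": "leek",
    "asparagus bean": "cowpea",
    "yardlong bean": "cowpea",
    "long bean": "cowpea",
    "mung bean sprout": "bean sprout",
    "soybean sprout": "bean sprout",
    "white radish": "radish",
    "daikon": "radish",
    "cabbage": "head cabbage",
    "green onion": "shallot",
    "scallion": "shallot",
    "spring onion": "shallot",
    "bitter gourd": "balsam pear",
    "bitter melon": "balsam pear",
    "zucchini": "cucurbita pepo",
    "winter gourd": "wax gourd",
    "winter melon": "wax gourd",
    "taro": "colocasia esculenta",
    "calabash": "bottle gourd",
    "sponge gourd": "luffa",
    "towel gourd": "luffa",
    "garland chrysanthemum": "chrysanthemum",
    "cilantro": "coriander",
}

# Canonical pesticide names (compounds recurring in national exceedance data).
PESTICIDES: tuple[str, ...] = (
    "clothianidin", "procymidone", "chlorpyrifos", "imidacloprid",
    "carbendazim", "acetamiprid", "thiamethoxam", "cypermethrin",
    "difenoconazole", "dimethoate", "omethoate", "phorate", "isocarbophos",
    "carbofuran", "abamectin", "chlorfenapyr", "lambda-cyhalothrin",
    "metalaxyl", "pyraclostrobin", "fipronil",
)

PESTICIDE_ALIASES: dict[str, str] = {
    "chlorpyriphos": "chlorpyrifos",
    "chlorpyrifos-ethyl": "chlorpyrifos",
    "mbc": "carbendazim",
    "carbendazol": "carbendazim",
    "dimethylformamidine": "procymidone",  # common transliteration slip
    "lambda cyhalothrin": "lambda-cyhalothrin",
    "cyhalothrin (lambda)": "lambda-cyhalothrin",
}

PROVINCES: tuple[str, ...] = tuple(p for p, _c, _lon, _lat in PROVINCIAL_CAPITALS)

PROVINCE_ALIASES: dict[str, str] = {
    "nei mongol": "Inner Mongolia",
    "neimenggu": "Inner Mongolia",
    "guangxi zhuang": "Guangxi",
    "ningxia hui": "Ningxia",
    "xinjiang uygur": "Xinjiang",
    "peking": "Beijing",
}


def _normalize(raw: str) -> str:
    return " ".join(str(raw).strip().lower().split())


def build_dictionary(
    canonical: tuple[str, ...] | list[str],
    aliases: Mapping[str, str] | None = None,
    *,
    preserve_case: bool = False,
) -> dict[str, str]:
    """Build a lookup from normalized spelling to canonical name.

    Canonical names map to themselves, which makes harmonization idempotent
    by construction. ``preserve_case`` keeps the canonical form's original
    capitalization (used for province names).
    """
    out: dict[str, str] = {}
    for name in canonical:
        canon = name if preserve_case else _normalize(name)
        out[_normalize(name)] = canon
    for raw, canon in (aliases or {}).items():
        key = _normalize(canon)
        if key not in out:
            raise ValueError(f"alias target {canon!r} is not a canonical name")
        out[_normalize(raw)] = out[key]
    return out


VEGETABLE_DICT = build_dictionary(VEGETABLES, VEGETABLE_ALIASES)
PESTICIDE_DICT = build_dictionary(PESTICIDES, PESTICIDE_ALIASES)
PROVINCE_DICT = build_dictionary(PROVINCES, PROVINCE_ALIASES, preserve_case=True)


def canonicalize_name(raw: str, dictionary: Mapping[str, str]) -> Optional[str]:
    """Map a raw spelling to its canonical name, or ``UNMAPPED`` (None).

    Deterministic and idempotent: a canonical name always maps to itself,
    and the result of a successful mapping is itself canonical.
    """
    if raw is None:
        return UNMAPPED
    key = _normalize(raw)
    if not key:
        return UNMAPPED
    return dictionary.get(key, UNMAPPED)
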