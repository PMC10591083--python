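"""Country-name handling for passport and registry tables.

Genebank passport data (MCPD) encodes origin countries as ISO 3166-1
alpha-3 codes (descriptor ORIGCTY), while floristic sources list English
country names.  Everything downstream of loading works in alpha-3.  The
lookup below covers the countries appearing in Euro+Med / GRIN native
ranges of the Brassica gene pool plus common historical and short-form
synonyms (e.g. "Syria" -> SYR, "Czechia" -> CZE).
"""

from __future__ import annotations

__all__ = ["to_alpha3", "alpha3_name", "is_alpha3", "UNKNOWN_ORIGIN"]

#: MCPD marker values that mean "origin unknown / not recorded".
UNKNOWN_ORIGIN = ""

_NAME_TO_ALPHA3: dict[str, str] = {
    "Albania": "ALB",
    "Algeria": "DZA",
    "Andorra": "AND",
    "Armenia": "ARM",
    "Austria": "AUT",
    "Belarus": "BLR",
    "Belgium": "BEL",
    "Bosnia and Herzegovina": "BIH",
    "Bulgaria": "BGR",
    "China": "CHN",
    "Croatia": "HRV",
    "Cyprus": "CYP",
    "Czech Republic": "CZE",
    "Democratic Republic of the Congo": "COD",
    "Denmark": "DNK",
    "Egypt": "EGY",
    "Eritrea": "ERI",
    "Estonia": "EST",
    "Ethiopia": "ETH",
    "Finland": "FIN",
    "France": "FRA",
    "Germany": "DEU",
    "Greece": "GRC",
    "Hungary": "HUN",
    "Iceland": "ISL",
    "Ireland": "IRL",
    "Israel": "ISR",
    "Italy": "ITA",
    "Jordan": "JOR",
    "Kenya": "KEN",
    "Korea": "KOR",
    "Latvia": "LVA",
    "Lebanon": "LBN",
    "Libya": "LBY",
    "Liechtenstein": "LIE",
    "Lithuania": "LTU",
    "Luxembourg": "LUX",
    "Malta": "MLT",
    "Mexico": "MEX",
    "Moldova": "MDA",
    "Montenegro": "MNE",
    "Morocco": "MAR",
    "Netherlands": "NLD",
    "North Macedonia": "MKD",
    "Norway": "NOR",
    "Poland": "POL",
    "Portugal": "PRT",
    "Romania": "ROU",
    "Russian Federation": "RUS",
    "Rwanda": "RWA",
    "Serbia": "SRB",
    "Slovakia": "SVK",
    "Slovenia": "SVN",
    "Spain": "ESP",
    "Sweden": "SWE",
    "Switzerland": "CHE",
    "Syria": "SYR",
    "Tanzania": "TZA",
    "Tunisia": "TUN",
    "Turkey": "TUR",
    "Uganda": "UGA",
    "Ukraine": "UKR",
    "United Kingdom": "GBR",
    "USA": "USA",
    "Yemen": "YEM",
    # historical / alternative forms commonly found in passport data
    "Czechia": "CZE",
    "Macedonia": "MKD",
    "Republic of Moldova": "MDA",
    "Moldova, Republic of": "MDA",
    "Russia": "RUS",
    "Syrian Arab Republic": "SYR",
    "Türkiye": "TUR",
    "Turkiye": "TUR",
    "UK": "GBR",
    "Great Britain": "GBR",
    "United States": "USA",
    "United States of America": "USA",
    "South Korea": "KOR",
    "Korea, Republic of": "KOR",
    "Republic of Korea": "KOR",
    "The Netherlands": "NLD",
    "Holland": "NLD",
    "Congo, Democratic Republic of the": "COD",
    "Zaire": "COD",
    "Tanzania, United Republic of": "TZA",
}

_LOWER_INDEX = {name.lower(): code for name, code in _NAME_TO_ALPHA3.items()}
_VALID_CODES = frozenset(_NAME_TO_ALPHA3.values())

_CODE_TO_NAME: dict[str, str] = {}
for _name, _code in _NAME_TO_ALPHA3.items():
    _CODE_TO_NAME.setdefault(_code, _name)


def is_alpha3(value: str) -> bool:
    """True if ``value`` looks like an ISO 3166-1 alpha-3 code."""
    return len(value) == 3 and value.isalpha() and value.isupper()


def to_alpha3(value: str) -> str | None:
    """Convert a country name or code to alpha-3; None if unresolvable.

    Accepts alpha-3 codes (passed through upper-cased), canonical English
    names and the bundled synonyms, case-insensitively.
    """
    value = value.strip()
    if not value:
        return None
    if len(value) == 3 and value.isalpha():
        code = value.upper()
        return code if code in _VALID_CODES else code  # unknown codes kept as-is
    return _LOWER_INDEX.get(value.lower())


def alpha3_name(code: str) -> str:
    """English name for an alpha-3 code (the code itself if unknown)."""
    return _CODE_TO_NAME.get(code.upper(), code)
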