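"""Standard InChIKey validation, FIKHB derivation and key generation.

A Standard InChIKey is 27 characters: a 14-letter first hash block encoding
molecular formula and atom connectivity (the basic, Mobile-H layer), a
hyphen, an 8-letter second block encoding the remaining layers, the
standard-flag pair "SA", a hyphen, and a single protonation-flag letter.
The 14-letter First InChIKey Hash Block (FIKHB) on its own identifies
molecules that share atom connectivity, which is what the whole
connectivity-search machinery keys on.

Two interchangeable key providers are offered:

* :class:`RDKitKeyProvider` — wraps the official InChI library embedded in
  RDKit, for interoperability with real-world keys;
* :class:`SurrogateKeyProvider` — a deterministic stand-in that hashes the
  basic layer into the first block and the remaining layers into the
  second, so the suite and synthetic fixtures run without any chemistry.

FIKHBs from different providers are incomparable; a registry records which
provider built it and refuses to mix.
"""

from __future__ import annotations

import hashlib
import re
from typing import Protocol, runtime_checkable

from . import inchi_core

_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{8}([A-Z]{2})-[A-Z]$")
_FIKHB_RE = re.compile(r"^[A-Z]{14}$")

FIKHB_LENGTH = 14
KEY_LENGTH = 27
PATTERN_MINUS_PROTON_LENGTH = 25  # full key minus "-<proton flag>"


class KeyValidationError(ValueError):
    """Raised when a string is not a well-formed Standard InChIKey."""


class ProviderError(RuntimeError):
    """Raised when a key provider cannot produce a key for an InChI."""


def validate_key(s: str) -> str:
    """Validate ``s`` as a Standard InChIKey and return it.

    Checks length 27, the letter/hyphen shape, and the standard flag pair
    "SA"; the error message names the violated rule.
    """
    if len(s) != KEY_LENGTH:
        raise KeyValidationError(
            f"InChIKey must be {KEY_LENGTH} characters, got {len(s)}: {s!r}"
        )
    m = _KEY_RE.match(s)
    if not m:
        raise KeyValidationError(
            f"InChIKey shape must be 14 letters '-' 10 letters '-' 1 letter: {s!r}"
        )
    if m.group(1) != "SA":
        raise KeyValidationError(
            f"flag pair {m.group(1)!r} is non-standard (Standard InChIKeys carry 'SA'): {s!r}"
        )
    return s


def fikhb_of(k: str) -> str:
    """First InChIKey Hash Block: the first 14 characters of a key.

    Accepts a full 27-character Standard InChIKey or a bare 14-letter
    block (idempotent on the latter).
    """
    if _FIKHB_RE.match(k):
        return k
    validate_key(k)
    return k[:FIKHB_LENGTH]


def pattern_of(k: str, b: int) -> str:
    """Search pattern for criterion B: the FIKHB (b=0) or the key minus its
    proton flag, i.e. the first 25 characters (b=1)."""
    if b == 0:
        return fikhb_of(k)
    if b == 1:
        if _FIKHB_RE.match(k):
            raise KeyValidationError(
                "pattern requires full key: criterion B=1 needs a 27-character InChIKey"
            )
        validate_key(k)
        return k[:PATTERN_MINUS_PROTON_LENGTH]
    raise ValueError(f"criterion B must be 0 or 1, got {b}")


@runtime_checkable
class KeyProvider(Protocol):
    """Contract for InChI -> Standard InChIKey generation.

    Implementations must be deterministic across runs and processes, and
    must give identical first blocks to InChIs with identical basic layers
    (formula + /c + /h + /q).
    """

    name: str
    deterministic: bool

    def key(self, inchi: str) -> str: ...


def key_for(inchi: str, provider: KeyProvider) -> str:
    """Generate and validate the Standard InChIKey for ``inchi``."""
    return validate_key(provider.key(inchi))


def key_for_parsed(p: "inchi_core.ParsedInChI", provider: KeyProvider) -> str:
    """Key an already-parsed InChI, avoiding a re-parse where the provider
    supports it (split children are keyed this way)."""
    key_parsed = getattr(provider, "key_parsed", None)
    if key_parsed is not None:
        return validate_key(key_parsed(p))
    return validate_key(provider.key(inchi_core.serialize(p)))


class RDKitKeyProvider:
    """Key provider backed by the official InChI library via RDKit."""

    name = "toolkit"
    deterministic = True

    def key(self, inchi: str) -> str:
        from rdkit import RDLogger
        from rdkit.Chem.inchi import InchiToInchiKey

        RDLogger.DisableLog("rdApp.*")
        out = InchiToInchiKey(inchi)
        if not out:
            raise ProviderError(f"InChI library could not key {inchi!r}")
        return out


def _letters(data: bytes, n: int) -> str:
    """Map a hash digest to ``n`` uppercase letters (base-26 on the digest)."""
    value = int.from_bytes(data, "big")
    out = []
    for _ in range(n):
        value, rem = divmod(value, 26)
        out.append(chr(ord("A") + rem))
    return "".join(out)


class SurrogateKeyProvider:
    """Hash-based key provider for hermetic tests and synthetic fixtures.

    The first block is a base-26 SHA-256 of the basic layer (formula +
    /c + /h + /q), which gives the basic-layer equality property by
    construction; the second block hashes the b/t/m/s/i layers; the proton
    flag encodes the /p value the way the real key does ('N' for none,
    'O','P',… for added protons, 'M','L',… for removed).  It makes no
    attempt to reproduce the official truncated-SHA algorithm bit-exactly.
    """

    name = "surrogate"
    deterministic = True

    def key(self, inchi: str) -> str:
        try:
            p = inchi_core.parse(inchi)
        except inchi_core.InChIParseError as exc:
            raise ProviderError(f"cannot key unparsable InChI {inchi!r}: {exc}") from exc
        return self.key_parsed(p)

    def key_parsed(self, p: inchi_core.ParsedInChI) -> str:
        first = _letters(hashlib.sha256(p.basic_layer().encode()).digest(), 14)
        rest = "".join(f"/{c}{p.layers[c]}" for c in "btmsi" if c in p.layers)
        second = _letters(hashlib.sha256(rest.encode()).digest(), 8)
        return f"{first}-{second}SA-{self._proton_flag(p.layers.get('p'))}"

    @staticmethod
    def _proton_flag(p_text: str | None) -> str:
        if not p_text:
            return "N"
        try:
            offset = int(p_text)
        except ValueError:
            return "A"
        code = ord("N") + offset
        if code < ord("A") or code > ord("Z"):
            return "A"
        return chr(code)


_PROVIDERS = {
    "toolkit": RDKitKeyProvider,
    "surrogate": SurrogateKeyProvider,
}


def get_provider(name: str) -> KeyProvider:
    """Instantiate a provider by its config name ('toolkit' or 'surrogate')."""
    try:
        return _PROVIDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown key provider {name!r}; choose from {sorted(_PROVIDERS)}"
        ) from None
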