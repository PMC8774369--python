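"""Codec for the canonical MNCD notation string.

The canonical ASCII dialect is::

    M<m>N<n>C<c>D<d> (<abcd>/<efgh>/<c>/<d>)-<X>

where ``m``/``n`` are the motor/non-motor subscripts (digit-sums of the
four-digit binary blocks ``abcd``/``efgh``), ``c``/``d`` the cognition and
dependency levels, and ``-<X>`` the optional time from symptom onset in
years.  Example: ``M2N3C2D2 (1010/1110/2/2)-20``.

Formatters are conservative (one canonical ASCII rendering); parsers are
liberal and also accept the typographic dialect seen in print — underscored
subscripts (``M_2_N_3_...``), a Unicode en-dash before the time suffix, and
flexible internal whitespace.  Parsing enforces the structural invariants:
each subscript must equal its block's digit-sum, and the parenthesized C/D
digits must agree with the subscripted ones.
"""

from __future__ import annotations

import re

from .core import MNCDRecord, MotorFlags, NonMotorFlags, motor_score, nonmotor_score

__all__ = ["format_notation", "parse_notation", "NotationError", "NotationConsistencyError"]


class NotationError(ValueError):
    """Malformed MNCD notation (grammar violation)."""


class NotationConsistencyError(NotationError):
    """Grammatically valid notation whose subscripts contradict its blocks."""


_BIN = r"[01]\s*[01]\s*[01]\s*[01]"
_NOTATION_RE = re.compile(
    r"""^\s*
    M\s*_?\s*(?P<m>\d)\s*_?\s*
    N\s*_?\s*(?P<n>\d)\s*_?\s*
    C\s*_?\s*(?P<c>\d)\s*_?\s*
    D\s*_?\s*(?P<d>\d)\s*_?\s*
    \(\s*(?P<mblock>{b})\s*/\s*(?P<nblock>{b})\s*/\s*(?P<cpar>\d)\s*/\s*(?P<dpar>\d)\s*\)
    \s*(?:[-–—]\s*(?P<time>\d+(?:\.\d+)?))?
    \s*\.?\s*$""".format(b=_BIN),
    re.VERBOSE,
)


def _format_time(years: float) -> str:
    """Integers print bare; fractional years print with up to 2 decimals."""
    if years == int(years):
        return str(int(years))
    return f"{years:.2f}".rstrip("0").rstrip(".")


def format_notation(record: MNCDRecord, include_time: bool = True) -> str:
    """Serialize a record to the canonical ASCII notation string.

    Subscripts are computed from the flag blocks, never taken on trust.
    ``include_time=True`` requires ``years_from_onset`` to be present;
    with ``include_time=False`` the ``-X`` suffix is omitted.
    """
    m = motor_score(record.motor)
    n = nonmotor_score(record.nonmotor)
    mblock = "".join(str(b) for b in record.motor.as_tuple())
    nblock = "".join(str(b) for b in record.nonmotor.as_tuple())
    text = (
        f"M{m}N{n}C{record.cognition}D{record.dependency} "
        f"({mblock}/{nblock}/{record.cognition}/{record.dependency})"
    )
    if include_time:
        if record.years_from_onset is None:
            raise NotationError(
                "include_time requested but the record has no years_from_onset"
            )
        text += f"-{_format_time(record.years_from_onset)}"
    return text


def parse_notation(text: str) -> MNCDRecord:
    """Parse a notation string (either dialect) into an :class:`MNCDRecord`.

    Raises :class:`NotationError` on grammar violations and
    :class:`NotationConsistencyError` (naming the offending axis) when a
    subscript disagrees with its block.
    """
    match = _NOTATION_RE.match(text)
    if match is None:
        raise NotationError(f"not a valid MNCD notation string: {text!r}")

    m_sub = int(match["m"])
    n_sub = int(match["n"])
    c_sub = int(match["c"])
    d_sub = int(match["d"])
    m_bits = tuple(int(ch) for ch in re.sub(r"\s", "", match["mblock"]))
    n_bits = tuple(int(ch) for ch in re.sub(r"\s", "", match["nblock"]))
    c_par = int(match["cpar"])
    d_par = int(match["dpar"])

    if not 0 <= c_sub <= 2:
        raise NotationError(f"axis C: subscript {c_sub} out of range 0..2")
    if not 0 <= d_sub <= 2:
        raise NotationError(f"axis D: subscript {d_sub} out of range 0..2")
    if m_sub != sum(m_bits):
        raise NotationConsistencyError(
            f"axis M: subscript {m_sub} does not equal the digit-sum "
            f"{sum(m_bits)} of block {''.join(map(str, m_bits))}"
        )
    if n_sub != sum(n_bits):
        raise NotationConsistencyError(
            f"axis N: subscript {n_sub} does not equal the digit-sum "
            f"{sum(n_bits)} of block {''.join(map(str, n_bits))}"
        )
    if c_sub != c_par:
        raise NotationConsistencyError(
            f"axis C: subscript {c_sub} disagrees with parenthesized value {c_par}"
        )
    if d_sub != d_par:
        raise NotationConsistencyError(
            f"axis D: subscript {d_sub} disagrees with parenthesized value {d_par}"
        )

    time_text = match["time"]
    years = float(time_text) if time_text is not None else None
    return MNCDRecord(
        motor=MotorFlags(*m_bits),
        nonmotor=NonMotorFlags(*n_bits),
        cognition=c_sub,
        dependency=d_sub,
        years_from_onset=years,
    )
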