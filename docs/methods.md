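# Methods

This note records the modeling and engineering decisions behind sbmlkit:
what each subsystem computes, the conventions fixed where the SBML
specifications leave freedom, what the synthetic documents do and do not
emulate, and the known limitations.

## Document model and canonical serialization

The object model maps each Level 3 core construct to a dataclass; notes,
annotations and elements of unsupported packages are held as generic XML
subtrees (qualified names in Clark notation, attribute order preserved)
so a write → read cycle reproduces their element/attribute/text sequence
exactly. User objects attached to any element are transient by contract:
they are excluded from structural equality and never serialized.

SBML permits many serialization dialects; sbmlkit fixes exactly one so
that byte-level golden tests are possible:

- UTF-8, two-space indentation, one element per line; foreign subtrees
  (notes, annotations, unknown packages) written compactly without
  re-indentation so text content is untouched;
- child elements in per-class schema order; attributes ordered `id`,
  `name`, then the remainder alphabetically by qualified name;
- doubles as the shortest decimal string that re-reads to the identical
  IEEE-754 value, with integral doubles of magnitude below 2^53 printed
  without a decimal point (`stoichiometry="1"`), and `INF`/`-INF`/`NaN`
  following the XML Schema lexical space;
- `sboTerm` as `SBO:` plus seven zero-padded digits;
- package namespaces declared on the root, sorted by prefix, each with
  its `required` flag (fbc/qual/groups default `false`, comp/arrays
  `true`); packages whose constructs are present are declared
  automatically at write time.

Identifier syntax (`[A-Za-z_][A-Za-z0-9_]*`) is enforced when an `id` is
assigned, not merely at validation time — malformed ids fail fast, which
mirrors strict reference behavior and keeps later passes simpler.
Duplicate metaids abort serialization. Reading accepts both L3V1 and
L3V2 namespaces and the writer re-emits the document's own declared
version (V1 reactions carry the retired mandatory `fast="false"`).

## Math

The infix grammar (loosest to tightest): `||`/`or`; `&&`/`and`;
`!`/`not`; `== != < <= > >=`; `+ -`; `* / %`; unary minus; `^`
(right-associative); call/parentheses/literals. Unary minus binds looser
than `^`, so `-2^2 = -4`. Decisions fixed here:

- single-argument `log` is base 10 by default, switchable to `ln` or to
  a hard error through `ParserSettings` — the reference Level 3 parser
  makes this configurable, and base 10 is its default;
- `a % b` is lowered at parse time to
  `piecewise(a − b·ceiling(a/b), xor(a<0, b<0), a − b·floor(a/b))`, the
  standard encoding whose result follows the dividend's sign, because
  L3V1 content MathML has no remainder symbol;
- unary plus is dropped; nested `plus`/`times` (and `and`/`or`) chains
  are flattened into n-ary nodes with stable child order;
- a numeric literal followed by a bare identifier takes that identifier
  as its declared units (`4.5 mole`); keywords (`and`, `or`, …) are
  never consumed as units;
- `true/false/INF/NaN` are case-insensitive tokens; `pi` and
  `exponentiale` must be lowercase so that ordinary identifiers like
  `Pi` stay available;
- `rateOf` is recognized on read and rejected by the evaluator — no
  derivative semantics are provided; `delay` likewise has no evaluation
  semantics (no history);
- rational literals (from `<cn type="rational">`) have no loss-free
  infix form; they serialize as an integer quotient, the one documented
  kind that does not round-trip through infix.

The serializer emits minimal parentheses such that re-parsing
reconstructs the same tree; the MathML bridge is bijective on the
supported content subset, with csymbols keyed by definition URL and
`sbml:units` carrying declared units. Evaluation follows IEEE-754 double
semantics (division by zero gives signed infinity, overflow saturates,
domain errors give NaN); function applications beta-reduce the bound
lambda with arity checking. Substitution is capture-avoiding: lambda
bound variables shadow the mapping and are alpha-renamed when a
replacement subtree would be captured.

## Units

Canonical form is a positive prefactor plus a map from SI base kinds
(kilogram, metre, second, ampere, kelvin, mole, candela, and the
counting pseudo-kind item) to exact rational exponents; gram and litre
are pre-expanded (10⁻³ kg, 10⁻³ m³), every derived kind is expanded to
its SI definition, radian/steradian fold to dimensionless, and the
`avogadro` kind becomes the pure number 6.02214179×10²³ (the value fixed
by Level 3). Exponents are `Fraction`s so that roots of powers are
lossless; the SBML attribute is a double, so non-unit denominators are
written as doubles with a warning. The algebra is purely multiplicative
(Level 3 has no Celsius and no affine units). *Equivalent* compares
exponent maps only; *identical* additionally compares prefactors to
1e-9 relative. "Merging" two definitions means canonicalize → multiply →
re-expand to a minimal kind-sorted term list, which keeps serialization
deterministic. Unit derivation for expressions uses equivalence (not
identity) for addition/comparison checks — the laxer and more useful
reading — and reports inconsistencies as warnings without ever throwing;
`power` needs a dimensionless base or a statically evaluable
dimensionless exponent, transcendental functions demand and yield
dimensionless, and `floor`/`ceiling`/`abs` pass units through.

## Identifier scopes

Five scope kinds: model SIds (shared by core elements and the fbc, qual,
comp, groups package elements), unit ids, local parameters per kinetic
law, ports per model, and array dimension ids per arrayed element — the
narrowest reading consistent with the arrays draft. A token may recur
across scope kinds without conflict. The document scan collects *all*
conflicts rather than failing fast, which is what a validator report
needs. "Reconciliation" is detection by default; an explicit
`auto_rename` applies the deterministic fresh-id rule (`base`, `base_1`,
`base_2`, …) to duplicated model SIds.

## Hierarchical composition

Flattening is recursive and bottom-up. Per submodel: instantiate the
referenced model definition (deep copy, itself flattened first), apply
deletions, then prefix every model-namespace SId, unit id and metaid
with `<submodelId>__` (double underscore: human-readable, valid SId
material, collisions resolved by the fresh-id rule), rewriting every
reference including names inside math and declared units on literals.
Deletions are applied before replacements, and `replacedElement` before
`replacedBy` — the order changes outcomes, so it is fixed.
`replacedElement` deletes the submodel target and redirects references
to the parent element's id; `replacedBy` deletes the parent element and
redirects references to the (prefixed) submodel element. Afterwards all
composition constructs are dropped and the identifier scan must come
back clean. Time/extent conversion factors are supported only when they
reference constant parameters — the minimal sound subset: kinetic-law
math is multiplied by extent-factor/time-factor, rate-rule math divided
by the time factor, and occurrences of the time csymbol replaced by
time/time-factor. Anything beyond that is a clear not-supported error.
External model definitions resolve through relative local file paths
only; URI schemes are rejected.

## Arrays

A dimension's size must reference a constant non-negative-integer
parameter; ordinals must be 0..k−1 without gaps; inner elements inherit
outer dimension ids, and redeclaration is a shadowing error. Static
validation checks every index expression by exhaustive enumeration of
the admissible assignment space, refusing above 10⁶ combinations — a
desk-scale guard that keeps the check exact. Expansion is row-major with
dimension 0 slowest; scalar copies are named `<id>_<i0>_<i1>…`
(underscore mangling, fresh-id fallback). Inside each copy dimension ids
become integer literals, `selector` applications over arrayed ids
collapse to the scalar name, and `Index` objects on SIdRef attributes
are evaluated and rewritten. A surviving reference to an arrayed element
without an index is an error. Flat documents are fixed points of the
expansion. When both transforms are requested, composition is flattened
before arrays, since submodel instantiation can introduce arrayed
elements. Event arrays are expanded structurally; no semantics beyond
structure are asserted for them.

## Qualitative models

Function terms are tried in document order; the first whose condition is
true supplies the result level, otherwise the default term. Conditions
must evaluate to booleans (levels are bound as numbers; booleans coerce
false=0/true=1 inside arithmetic). The synchronous scheme reads one
state and applies all assignment-level outputs simultaneously;
consumption/production transition effects are rejected as unsupported
semantics rather than silently approximated. A result level above the
output species' declared maximum is an error, not a clamp — the draft
treats it as invalid, and clamping would silently change dynamics. The
state space is the complete deterministic graph over all level
combinations (refused above a configurable node budget); attractors are
its terminal strongly-connected components, computed with networkx.

## Flux balance constraints

GPR trees use the conventional grammar — `and` tighter than `or`,
case-insensitive keywords, parentheses — while the XML association tree
remains the normative encoding. The stoichiometric matrix is exported
sparse (SciPy CSC), species × reactions in document order, products
positive; boundary species stay in the matrix but are listed for
masking. Strict-mode checks cover missing/unknown/non-constant/NaN
bounds, inverted bound pairs and objectives over unknown reactions.
fbc version 2 is the supported encoding; version 1 documents are
rejected with an explicit message. Solving the optimization itself is
out of scope.

## Validation

Categories: identifiers, references, math (arity, free symbols,
function-call arity against definitions), units, fbc, qual, comp,
arrays. Unit inconsistencies are always warnings — SBML treats unit
agreement as best practice, not validity. Rule ids (`CORE-NNNNN`,
`FBC-…`, `QUAL-…`, `COMP-…`, `ARR-…`) are sbmlkit's own stable scheme; a
partial correspondence with the official validation rule numbers exists
but is not guaranteed complete. Reports are sorted by (path, rule id)
and are byte-identical across runs on the same document.

## Synthetic documents

The fixture generator drives all randomness through one
`random.Random(seed)` — no global state — and emits L3V1 by default
(L3V2 behind a toggle). Default sizes are desk-scale: 5 species, 4
reactions, 3 constant parameters, 1 assignment rule, kinetic laws of
math depth 2–3 over the reaction's own reactants and a rate parameter,
Boolean qualitative species (3 by default) with one writer transition
each, 1–2 submodels instantiating a small shared definition with one
port-mediated replacement, and 1-D arrays of size 2–3 with an indexed
reaction over an arrayed species. These sizes keep exhaustive oracles
(truth tables, index enumeration) exact while exercising every
construct; they are not meant to model the statistics of curated
repository models. In particular the generator does not emulate deep
annotation trees, large irregular stoichiometries, algebraic-rule
systems, delay kinetics or multi-level (non-Boolean) logical models —
passing tests demonstrate structural and semantic correctness of the
transformations at desk scale, not performance or coverage of every
construct combination found in the wild. The golden corpus provides the
hand-auditable cases: one document per construct family, a two-level
hierarchical model with its hand-verified flattening frozen in, a 2×2
array grid with reaction indexing, and defective documents whose exact
diagnostic lists are part of the contract.

## Numerical and procedural choices

- Double formatting uses Python's shortest-repr guarantee; equality in
  structural comparison is exact (no tolerance), which is what a
  round-trip contract needs.
- Unit prefactor comparison uses 1e-9 relative tolerance; evaluator
  agreement in tests is checked to 1e-12 relative.
- Tie-break for overlapping qualitative function terms: document order.
- Attractor and scope tables are sorted before comparison or output, so
  no result depends on hash or enumeration order.
- Problem sizes in the acceptance script (200 documents, 1000 formulas,
  300 unit expressions, 50 hierarchies, 50 arrayed models, 12 logical
  networks, 60 association trees) are the package's standard desk-scale
  verification corpus; every quantity is recomputed from the given seed
  at run time.

## Known limitations

- Packages beyond the five supported ones (layout, render, spatial,
  distrib, dyn, req, multi) round-trip as preserved XML but get no typed
  model or semantics.
- No ODE/stochastic simulation, no FBA solving, no symbolic
  simplification or derivatives.
- comp conversion factors beyond constant parameters, and `replacedBy`
  chains deeper than one level per element, are rejected rather than
  approximated.
- Unit conversion of quantities (rescaling values to new units) is out
  of scope; only the algebra of the units themselves is implemented.
- Annotation content is preserved, not interpreted (no MIRIAM/URI
  qualifier model).
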