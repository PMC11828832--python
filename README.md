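# chatmeta

Privacy-preserving minimization and social-interaction analysis of
messaging exports.

`chatmeta` parses WhatsApp per-chat text exports (across locale-dependent
header dialects) and Facebook/Instagram "Download Your Information" JSON
archives, reduces them to fully de-identified metadata — pseudonymous
IDs, timestamps, word counts and voice-message durations, with no plain
text retained — and computes social-interaction statistics on the result:

- **interactivity filter** — a chat is kept when no single partner
  contributed more than 90% of its words;
- **interaction bias** — `0.5 − w_sent/(w_sent + w_received)` per dyad
  (0 balanced, −0.5 donor-only, +0.5 contact-only);
- **Gini heterogeneity** — inequality of donor-sent word counts across
  contacts, `g = 2·Σ j·V_j / (k·Σ V_j) − (k+1)/k` on the
  ascending-sorted vector;
- **burstiness** — `B1 = (r−1)/(r+1)` with `r = σ/μ` over day-level
  inter-event times, for chats with at least ten interaction days;
- **donor feedback** — words sent/received over time (received totals
  suppressed in any window with fewer than two active contacts), active
  hours, and reply latencies.

A synthetic-data module generates raw conversations with controllable
balance, contact heterogeneity and day-gap burstiness, and renders them
in the real export formats for round-trip and privacy testing. All
generated names and content come from a closed sentinel vocabulary, so a
leakage audit of any minimized output is exhaustive.

## CLI

```sh
# generate a synthetic WhatsApp fixture (5 chats, ground truth alongside)
chatmeta simulate --platform whatsapp --n-chats 5 --days 30 --seed 1 --out fixtures/

# de-identify an export into a donation (JSON + CSV + leakage audit)
chatmeta minimize --input fixtures/ --donor-name "Vexalor Quint" --seed 1 --out donation/

# per-chat / per-participant / per-platform metric tables
chatmeta analyze --input donation/ --seed 1 --out metrics/

# donor-facing feedback summaries
chatmeta feedback --input donation/donation.json --out feedback/

# audit a serialized donation against a sentinel vocabulary
chatmeta audit --donation donation/donation.json --vocab fixtures/ground_truth.json
```

Exit codes: 0 ok, 1 usage error, 2 parse failure, 3 privacy-audit
failure. A YAML config file (`--config`) can supply defaults; flags
override it. Logs never contain message content or participant names.

## Package layout

- `chatmeta.chat_formats` — WhatsApp dialect detection/parsing, Meta
  archive parsing, mojibake repair, per-language marker tables
- `chatmeta.minimizer` — pseudonymization, minimization, period
  restriction, serialization, leakage audit
- `chatmeta.metrics` — interactivity, bias, Gini, burstiness, summaries,
  contact resampling, CSV ingestion
- `chatmeta.feedback` — intensity series, active hours, response times
- `chatmeta.synthetic` — conversation/network simulators and export
  renderers
- `chatmeta.cli` — `chatmeta` command group
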