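// Phase 2: cognitive-score extraction markup.  Requires Token annotations
// plus the MonthName/Weekday annotations from the DatesLexical phase.
//
// Under appelt control the longest match at each position wins, so a full
// numeric date ("12/03/2010", 5 tokens) outcompetes the score pattern
// ("12/03", 3 tokens) at the same start, and "12 March 2010" outcompetes
// the bare month-name date.

Phase: MMSE
Input: Token MonthName Weekday
Options: control=appelt

// -- assessment triggers ---------------------------------------------------

Rule: TriggerLongForm
Priority: 20
(
  ({Token.string=="Mini"}|{Token.string=="mini"}|{Token.string=="MINI"})
  ({Token.string=="-"})?
  ({Token.string=="Mental"}|{Token.string=="mental"}|{Token.string=="MENTAL"})
  ({Token.string=="State"}|{Token.string=="state"}|{Token.string=="STATE"})
  ({Token.string=="Examination"}|{Token.string=="examination"}|{Token.string=="Exam"}|{Token.string=="exam"})
):t
--> :t.MMSETrigger = {form = "long"}

Rule: TriggerShortForm
Priority: 10
({Token.string=="MMSE"}):t
--> :t.MMSETrigger = {form = "short"}

// -- date expressions ------------------------------------------------------

Rule: DateNumericSlash
Priority: 30
(
  ({Token.kind=="number"})({Token.string=="/"})({Token.kind=="number"})({Token.string=="/"})({Token.kind=="number"})
):d
--> :d.DateExpr = {kind = "numeric"}

Rule: DateNumericDash
Priority: 30
(
  ({Token.kind=="number"})({Token.string=="-"})({Token.kind=="number"})({Token.string=="-"})({Token.kind=="number"})
):d
--> :d.DateExpr = {kind = "numeric"}

Rule: DateDayMonthYear
Priority: 25
(
  ({Token.kind=="number"})({MonthName}):m({Token.kind=="number"})
):d
--> :d.DateExpr = {kind = "dmy", month = :m@month}

Rule: DateMonthYear
Priority: 22
(
  ({MonthName}):m({Token.kind=="number"})
):d
--> :d.DateExpr = {kind = "my", month = :m@month}

Rule: DateDayMonth
Priority: 22
(
  ({Token.kind=="number"})({MonthName}):m
):d
--> :d.DateExpr = {kind = "dm", month = :m@month}

Rule: DateMonthOnly
Priority: 20
(({MonthName}):m):d
--> :d.DateExpr = {kind = "month", month = :m@month}

Rule: DateWeekday
Priority: 20
(({Weekday}):w):d
--> :d.DateExpr = {kind = "weekday", dow = :w@dow}

// -- score pattern ---------------------------------------------------------

Rule: Score
Priority: 10
(
  (({Token.kind=="number"}):n)({Token.string=="/"})(({Token.kind=="number"}):den)
):s
--> :s.MMSEScore = {num = :n@string, den = :den@string}
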