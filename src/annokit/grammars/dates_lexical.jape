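// Phase 1: mark month names and weekday names over Token annotations.
// Month numbers and weekday indices (Monday=0) are attached as features so
// the date normalizer never re-parses the names.

Phase: DatesLexical
Input: Token
Options: control=appelt

Rule: MonthJanuary
({Token.string=="January"}|{Token.string=="january"}|{Token.string=="Jan"}|{Token.string=="jan"}):m
--> :m.MonthName = {month = 1}

Rule: MonthFebruary
({Token.string=="February"}|{Token.string=="february"}|{Token.string=="Feb"}|{Token.string=="feb"}):m
--> :m.MonthName = {month = 2}

Rule: MonthMarch
({Token.string=="March"}|{Token.string=="march"}|{Token.string=="Mar"}|{Token.string=="mar"}):m
--> :m.MonthName = {month = 3}

Rule: MonthApril
({Token.string=="April"}|{Token.string=="april"}|{Token.string=="Apr"}|{Token.string=="apr"}):m
--> :m.MonthName = {month = 4}

Rule: MonthMay
({Token.string=="May"}|{Token.string=="may"}):m
--> :m.MonthName = {month = 5}

Rule: MonthJune
({Token.string=="June"}|{Token.string=="june"}|{Token.string=="Jun"}|{Token.string=="jun"}):m
--> :m.MonthName = {month = 6}

Rule: MonthJuly
({Token.string=="July"}|{Token.string=="july"}|{Token.string=="Jul"}|{Token.string=="jul"}):m
--> :m.MonthName = {month = 7}

Rule: MonthAugust
({Token.string=="August"}|{Token.string=="august"}|{Token.string=="Aug"}|{Token.string=="aug"}):m
--> :m.MonthName = {month = 8}

Rule: MonthSeptember
({Token.string=="September"}|{Token.string=="september"}|{Token.string=="Sep"}|{Token.string=="sep"}|{Token.string=="Sept"}|{Token.string=="sept"}):m
--> :m.MonthName = {month = 9}

Rule: MonthOctober
({Token.string=="October"}|{Token.string=="october"}|{Token.string=="Oct"}|{Token.string=="oct"}):m
--> :m.MonthName = {month = 10}

Rule: MonthNovember
({Token.string=="November"}|{Token.string=="november"}|{Token.string=="Nov"}|{Token.string=="nov"}):m
--> :m.MonthName = {month = 11}

Rule: MonthDecember
({Token.string=="December"}|{Token.string=="december"}|{Token.string=="Dec"}|{Token.string=="dec"}):m
--> :m.MonthName = {month = 12}

Rule: WeekdayMonday
({Token.string=="Monday"}|{Token.string=="monday"}):d
--> :d.Weekday = {dow = 0}

Rule: WeekdayTuesday
({Token.string=="Tuesday"}|{Token.string=="tuesday"}):d
--> :d.Weekday = {dow = 1}

Rule: WeekdayWednesday
({Token.string=="Wednesday"}|{Token.string=="wednesday"}):d
--> :d.Weekday = {dow = 2}

Rule: WeekdayThursday
({Token.string=="Thursday"}|{Token.string=="thursday"}):d
--> :d.Weekday = {dow = 3}

Rule: WeekdayFriday
({Token.string=="Friday"}|{Token.string=="friday"}):d
--> :d.Weekday = {dow = 4}

Rule: WeekdaySaturday
({Token.string=="Saturday"}|{Token.string=="saturday"}):d
--> :d.Weekday = {dow = 5}

Rule: WeekdaySunday
({Token.string=="Sunday"}|{Token.string=="sunday"}):d
--> :d.Weekday = {dow = 6}
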