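# Default action taxonomy: raw audit-log action types -> (action label, portal function).
#
# Two sections per function:
#   * canonical action labels (match on the label string itself), and
#   * raw log-string rules ("match" differing from the label), which are
#     SITE-EDITABLE: the raw vocabulary emitted by the portal server varies
#     by vendor version and institutional configuration, so the raw rules
#     shipped here cover the vocabulary seen in typical exports and are a
#     starting point, not ground truth.
#
# Matching is case-insensitive on trimmed strings.  "extended" restricts a
# rule to given UA_EXTENDED_INFO values; "fallback: true" marks the rule
# that applies when no extended-info rule of the same action pattern fires.

functions:
  Messaging:
    - label: Letters
    - label: Message center
    - label: Send new message
    # raw log strings
    - label: Send new message
      match: Messaging
      extended: [Medadvice-form, Send new message]
    - label: Message center
      match: Messaging
      extended: [Inbox message list, Message read]
    - label: Message center
      match: Messaging
      fallback: true

  Visits:
    - label: Appointment details
    - label: Cancel an appointment
    - label: Driving directions
    - label: eCheck-in
    - label: Schedule an appointment
    - label: Telemedicine
    - label: Upcoming tests
    # raw log strings
    - label: Appointment details
      match: Visits
    - label: Appointment details
      match: Encounter Details
    - label: Schedule an appointment
      match: Provider List Widget

  My record:
    - label: Allergies
    - label: Current health issues
    - label: Flowsheet
    - label: Health summary
    - label: Immunizations
    - label: Medications
    - label: My conditions
    - label: Preventive care
    - label: Test results

  Medical tools:
    - label: Consolidate EMR
    - label: Download my record
    - label: Research studies
    - label: Share my record
    - label: Wallet card
    - label: Who accessed my record

  Billing:
    - label: Bill payment
    - label: Billing account details
    - label: Billing account summary
    - label: Change paperless status
    - label: Estimates
    - label: Insurance summary
    - label: Update insurance

  Resources:
    - label: Patient education
    - label: Terms and conditions

  Proxy:
    - label: Proxy forms
    - label: Proxy renewal request
    - label: Request child proxy access
    - label: Request proxy access
    - label: Switch proxy context

  Preferences:
    - label: About me
    - label: Manage my accounts
    - label: Notifications
    - label: Personalize
    - label: Security settings

# Auxiliary events: flagged for sessionization, excluded from usage metrics.
miscellaneous:
  - label: Login
    flag: login
    match: [Login, Log in, MYC_LOGIN]
  - label: Logout
    flag: logout
    match: [Logout, Log out, MYC_LOGOUT]
  - label: Two-factor authentication
    flag: two_factor
    match: [Two-factor authentication, 2FA, Two factor]
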