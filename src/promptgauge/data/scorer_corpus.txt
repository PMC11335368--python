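Thank you for your message. I reviewed your question and your recent results.
Your recent lab results are within the normal range and no further testing is
needed at this time. Please continue taking your current medications as
prescribed and let us know if your symptoms change or get worse. If you notice
new symptoms such as fever, chest pain, or shortness of breath, please call
the clinic or seek urgent care right away.

It is common to have mild soreness after the procedure for a few days. You can
use an over the counter pain reliever as directed on the label. Drink plenty
of fluids and rest as needed. If the pain is severe or does not improve,
please schedule a visit so we can take a closer look.

I am happy to refill your medication. The refill has been sent to your
pharmacy and should be ready later today. Please take the medication with food
to reduce stomach upset. If you have any side effects such as a rash,
swelling, or trouble breathing, stop the medication and contact us right away.

Your question about the paperwork has been forwarded to our front desk team.
The completed form will be available in your portal within three business
days. If you need the form sooner, please call the office and we will do our
best to help.

Thank you for letting us know about your blood pressure readings at home. The
numbers you shared look well controlled. Please keep taking your medicine at
the same dose and keep checking your pressure once or twice a week. We will
review everything at your next visit.

It sounds like you may have a mild viral illness. Most people feel better in a
week with rest, fluids, and time. Antibiotics do not help with a viral
infection. If your fever lasts more than three days, or if you feel much
worse, please contact us again or schedule an appointment.

I understand your concern and I am glad you reached out. Based on your chart
and the note from your last visit, this plan is safe to continue. We will
order the follow up test you asked about and the results will appear in your
portal. Please do not hesitate to write again with any other questions. Take
care and be well.
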